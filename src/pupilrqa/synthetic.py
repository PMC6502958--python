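"""Synthetic pupil recordings and cohorts with known ground truth.

The recording generator emulates a 15-minute dark-adapted pupillometry
session sampled at a nominal 240 Hz: a mm-scale baseline diameter modulated
(in percent units) by a slow drift, low-frequency (< 0.15 Hz) and
high-frequency (0.15-0.45 Hz) sinusoidal components, white Gaussian noise
and an optional 1/f component, with blinks written as contiguous runs of
zero diameter and spikes as impulsive outliers — matching the device
convention that a zero sample encodes a blink.

It targets the statistical structure the analysis pipeline consumes, not a
physiological light-reflex model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .io_preprocess import RawPupilRecording


@dataclass
class SynthesisParams:
    """Parameters of a synthetic dark-condition pupil recording.

    Frequencies are Hz, amplitudes are percent of baseline, phases radians.
    LF component frequencies must lie below 0.15 Hz and HF components within
    [0.15, 0.45] Hz; ``duration`` must be at least 120 s so the slow band is
    resolvable.
    """

    duration: float = 900.0
    fs: float = 240.0
    baseline_mm: float = 5.0
    lf_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.05, 1.5, 0.0), (0.10, 1.0, 1.2)])
    hf_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.25, 0.8, 0.4), (0.35, 0.5, 2.1)])
    noise_sd: float = 0.3
    pink_noise_sd: float = 0.0
    blink_rate: float = 12.0       # events/minute
    blink_duration: float = 0.2    # seconds
    spike_rate: float = 2.0        # events/minute
    spike_amplitude: float = 8.0   # percent units
    drift_amplitude: float = 2.0   # percent units
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.duration < 120:
            raise DomainError("duration must be >= 120 s for band analysis")
        if any(f >= 0.15 for f, _, _ in self.lf_components):
            raise DomainError("LF component frequencies must be < 0.15 Hz")
        if any(not 0.15 <= f <= 0.45 for f, _, _ in self.hf_components):
            raise DomainError("HF component frequencies must be in "
                              "[0.15, 0.45] Hz")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    lf_pct: np.ndarray
    hf_pct: np.ndarray
    clean_diameter: np.ndarray
    blink_idx: np.ndarray
    spike_idx: np.ndarray
    baseline: float


def generate_recording(params: SynthesisParams
                       ) -> tuple[RawPupilRecording, GroundTruth]:
    """Build a raw recording plus its ground truth; fully seed-determined."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs

    lf = np.zeros(n)
    for f, a, ph in p.lf_components:
        lf += a * np.sin(2 * np.pi * f * t + ph)
    hf = np.zeros(n)
    for f, a, ph in p.hf_components:
        hf += a * np.sin(2 * np.pi * f * t + ph)
    drift = p.drift_amplitude * np.cos(2 * np.pi * t / (2 * p.duration))

    pct = drift + lf + hf
    if p.noise_sd > 0:
        pct = pct + rng.normal(0.0, p.noise_sd, n)
    if p.pink_noise_sd > 0:
        pct = pct + p.pink_noise_sd * _pink_noise(n, rng)

    clean = p.baseline_mm * (1.0 + pct / 100.0)
    diameter = clean.copy()

    n_blinks = rng.poisson(p.blink_rate * p.duration / 60.0)
    blink_idx: list[int] = []
    blink_len = max(1, int(round(p.blink_duration * p.fs)))
    for start in rng.integers(0, max(n - blink_len, 1), size=n_blinks):
        sl = slice(int(start), int(start) + blink_len)
        diameter[sl] = 0.0
        blink_idx.extend(range(sl.start, min(sl.stop, n)))

    n_spikes = rng.poisson(p.spike_rate * p.duration / 60.0)
    spike_idx = rng.integers(0, n, size=n_spikes)
    signs = rng.choice([-1.0, 1.0], size=n_spikes)
    for i, s in zip(spike_idx, signs):
        if diameter[i] > 0:  # do not overwrite a blink zero
            diameter[i] = max(
                diameter[i] * (1.0 + s * p.spike_amplitude / 100.0), 0.01)

    rec = RawPupilRecording(time=t, diameter=diameter, fs_nominal=p.fs)
    truth = GroundTruth(
        lf_pct=lf, hf_pct=hf, clean_diameter=clean,
        blink_idx=np.unique(np.asarray(blink_idx, dtype=int)),
        spike_idx=np.asarray(sorted(set(int(i) for i in spike_idx)), int),
        baseline=float(clean[t <= t[0] + 60.0].max()))
    return rec, truth


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def generate_coupled_pair(freq: float, coupling: float, n: int, rate: float,
                          seed: int | None = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Two oscillatory series with tunable dynamical coupling.

    Series A is a noisy sinusoid. Series B mixes a phase-locked copy of A
    (weight ``coupling``) with a spectrum-matched but phase-randomized
    surrogate of A (weight ``1 - coupling``): coupling 1 gives B == A, and
    coupling 0 gives an independent series with the same power spectrum.
    """
    if not 0.0 <= coupling <= 1.0:
        raise DomainError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    a = np.sin(2 * np.pi * freq * t) + 0.05 * rng.normal(size=n)
    spec = np.fft.rfft(a)
    phases = rng.uniform(0, 2 * np.pi, len(spec))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    surrogate = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n)
    b = coupling * a + (1.0 - coupling) * surrogate
    return a, b


def generate_cohort(n: int, target_corr: np.ndarray, marginals: list,
                    seed: int | None = 0,
                    columns: list[str] | None = None):
    """Gaussian-copula cohort draw with prescribed margins.

    ``marginals`` is one inverse-CDF callable (u in (0, 1) -> value) per
    column. The latent correlation must be positive semi-definite.
    """
    import pandas as pd
    from .population_stats import nearest_psd

    C = np.asarray(target_corr, dtype=float)
    k = C.shape[0]
    if len(marginals) != k:
        raise DomainError("one marginal per correlation column required")
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -1e-8:
        raise DomainError("target correlation is not positive semi-definite")
    C = nearest_psd(C)
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(k), C, size=n, method="eigh")
    from scipy import stats as sstats
    u = sstats.norm.cdf(z)
    data = {f"c{j}" if columns is None else columns[j]:
            np.asarray(marginals[j](u[:, j]))
            for j in range(k)}
    return pd.DataFrame(data)
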