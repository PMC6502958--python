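"""Empirical mode decomposition and autonomic band aggregation.

The percent-change series is split into intrinsic mode functions (IMFs) by
sifting; each IMF's dominant frequency is estimated from a MUSIC
pseudospectrum and the IMF is assigned to the low-frequency (LF, 0-0.15 Hz)
or high-frequency (HF, 0.15-0.45 Hz) autonomic band, or discarded when its
dominant frequency exceeds 0.45 Hz. Retained IMFs are summed per band.

EMD defaults follow the canonical sifting recipe: cubic-spline envelopes
through local extrema, mirror extension of the two outermost extrema at each
boundary, Huang's standard-deviation stopping criterion (SD < 0.2 between
successive siftings), at most 10 siftings per IMF and at most 12 IMFs. The
decomposition is complete by construction: the IMFs plus the final residual
sum back to the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import DegenerateInputError, DomainError, EmptyBandError

LF_BAND = (0.0, 0.15)
HF_BAND = (0.15, 0.45)

BandLabel = Literal["LF", "HF", "discard"]


@dataclass
class IMF:
    """One intrinsic mode function with its spectral classification."""

    values: np.ndarray
    dominant_freq: float | None = None
    band_label: BandLabel | None = None


@dataclass
class BandComponents:
    """Aggregated LF and HF series (elementwise sums of member IMFs)."""

    lf: np.ndarray
    hf: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if len(self.lf) != len(self.hf):
            raise DomainError("lf and hf must have equal length")


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateaus use their midpoint."""
    dx = np.diff(x)
    # collapse exact plateaus so that sign changes are detectable
    sign = np.sign(dx)
    nonzero = sign != 0
    if not nonzero.any():
        return np.array([], int), np.array([], int)
    # forward-fill zero signs with the previous nonzero slope
    filled = sign.copy()
    last = 0.0
    for i, s in enumerate(filled):
        if s == 0:
            filled[i] = last
        else:
            last = s
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _mirror_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema with 2-point mirror extension."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema about each end point
    k = min(2, len(idx))
    pts_t = [-t[:k][::-1], t, 2 * (n - 1) - t[-k:][::-1]]
    pts_v = [v[:k][::-1], v, v[-k:][::-1]]
    tt = np.concatenate(pts_t)
    vv = np.concatenate(pts_v)
    keep = np.concatenate([[True], np.diff(tt) > 0])
    cs = CubicSpline(tt[keep], vv[keep])
    return cs(np.arange(n))


def emd(series: np.ndarray, max_imfs: int = 12, max_siftings: int = 10,
        sd_threshold: float = 0.2) -> tuple[list[IMF], np.ndarray]:
    """Sifting-based empirical mode decomposition.

    Returns ``(imfs, residual)`` with ``sum(imfs) + residual == series``
    exactly. Monotone or constant input yields zero IMFs and the input as
    residual.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise DegenerateInputError("series too short for EMD")
    residual = x.copy()
    imfs: list[IMF] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 3:
            break  # residual is (near-)monotone
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            upper = _mirror_envelope(h, mx)
            lower = _mirror_envelope(h, mn)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(IMF(values=h))
        residual = residual - h
    return imfs, residual


def music_dominant_freq(values: np.ndarray, rate: float,
                        signal_space_dim: int = 4, corr_order: int = 20,
                        grid_step: float = 0.005) -> float:
    """Dominant frequency as the argmax of a MUSIC pseudospectrum.

    An autocorrelation matrix of order ``corr_order`` is estimated from
    sliding windows, eigendecomposed, and the pseudospectrum
    ``1 / ||E_n^H e(f)||^2`` (noise-subspace projector) is evaluated on a
    frequency grid over [0, rate/2].
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8 * signal_space_dim:
        raise DegenerateInputError(
            f"series of length {x.size} too short for signal space dim "
            f"{signal_space_dim}")
    m = corr_order
    x = x - x.mean()
    # sliding windows -> sample autocorrelation matrix
    from numpy.lib.stride_tricks import sliding_window_view
    W = sliding_window_view(x, m)
    R = W.T @ W / W.shape[0]
    eigval, eigvec = np.linalg.eigh(R)
    noise = eigvec[:, : m - signal_space_dim]  # smallest eigenvalues
    freqs = np.arange(0.0, rate / 2 + grid_step / 2, grid_step)
    k = np.arange(m)
    steering = np.exp(-2j * np.pi * np.outer(freqs / rate, k))  # (F, m)
    proj = steering @ noise  # (F, m - p)
    power = 1.0 / np.maximum(np.sum(np.abs(proj) ** 2, axis=1), 1e-300)
    return float(freqs[np.argmax(power)])


def classify_imf(imf: IMF) -> BandLabel:
    """Assign LF / HF / discard from the dominant frequency.

    The 0.15 Hz boundary belongs to HF (the HF interval is closed on the
    left) so the band partition on [0, 0.45] is exhaustive and exclusive.
    """
    f = imf.dominant_freq
    if f is None:
        raise DomainError("dominant_freq not computed")
    if f < LF_BAND[1]:
        label: BandLabel = "LF"
    elif f <= HF_BAND[1]:
        label = "HF"
    else:
        label = "discard"
    imf.band_label = label
    return label


def aggregate_bands(imfs: list[IMF], rate: float) -> BandComponents:
    """Sum LF-labelled and HF-labelled IMFs into band components."""
    lf_members = [i.values for i in imfs if i.band_label == "LF"]
    hf_members = [i.values for i in imfs if i.band_label == "HF"]
    if not lf_members or not hf_members:
        missing = "LF" if not lf_members else "HF"
        raise EmptyBandError(
            f"no IMF classified into the {missing} band; subject not "
            "analyzable")
    return BandComponents(lf=np.sum(lf_members, axis=0),
                          hf=np.sum(hf_members, axis=0), rate=rate)


def decompose(series: np.ndarray, rate: float,
              signal_space_dim: int = 4, corr_order: int = 20,
              grid_step: float = 0.005) -> tuple[BandComponents, list[IMF],
                                                 np.ndarray]:
    """EMD -> MUSIC classification -> band aggregation, in one call."""
    imfs, residual = emd(series)
    for imf in imfs:
        imf.dominant_freq = music_dominant_freq(
            imf.values, rate, signal_space_dim, corr_order, grid_step)
        classify_imf(imf)
    bands = aggregate_bands(imfs, rate)
    return bands, imfs, residual
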