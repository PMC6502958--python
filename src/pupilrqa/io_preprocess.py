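"""Raw pupil-trace input and preprocessing.

Turns an eye-tracker export (time, pupil diameter; zeros encode blinks) into a
baseline-corrected percent-change series compressed to a uniform low rate.
The stages, in order: blink removal by linear interpolation, Hampel despiking,
zero-phase low-pass filtering, baseline extraction (maximum diameter over the
first minute in darkness), percent change relative to that baseline, and cubic
spline compression to ``target_rate`` samples per second.

The Hampel window width follows ``w = hampel_coeff * fs / f0`` with
``hampel_coeff = 0.44``, rounded to the nearest odd integer and clamped at 3 so
the moving median is centered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .exceptions import (
    DegenerateInputError,
    DomainError,
    EmptyInputError,
    FormatError,
)

log = logging.getLogger(__name__)

#: MAD-to-sigma consistency factor for Gaussian data.
MAD_SCALE = 1.4826


@dataclass
class RawPupilRecording:
    """A timestamped pupil-diameter trace.

    ``diameter`` is in device units (mm scale); samples equal to zero encode
    blinks. ``time`` is seconds from recording start and must be strictly
    increasing. Processing treats the trace as uniformly sampled at
    ``fs_nominal``; sub-millisecond timestamp jitter is ignored.
    """

    time: np.ndarray
    diameter: np.ndarray
    fs_nominal: float = 240.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.shape != self.diameter.shape:
            raise FormatError("time and diameter must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")
        if np.any(self.diameter < 0):
            raise DomainError("negative pupil diameters are not physical")

    def __len__(self) -> int:
        return self.diameter.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def replace(self, diameter: np.ndarray) -> "RawPupilRecording":
        return RawPupilRecording(self.time.copy(), np.asarray(diameter, float),
                                 self.fs_nominal)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``target_rate`` must satisfy the Nyquist criterion for the upper edge of
    the autonomic band (0.45 Hz), i.e. be at least 0.9 samples/s; the default
    5 Hz leaves ample margin.
    """

    f0: float = 2.0                 # low-pass cutoff, Hz
    hampel_coeff: float = 0.44      # window-width constant w = c * fs / f0
    baseline_window: float = 60.0   # seconds used for the baseline maximum
    target_rate: float = 5.0        # samples/s after spline compression
    nsigma: float = 3.0             # Hampel threshold in scaled-MAD units

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise DomainError("f0 must be positive")
        if self.target_rate < 2 * 0.45:
            raise DomainError(
                "target_rate below the Nyquist rate for the 0.45 Hz band edge")


@dataclass
class PercentChangeSeries:
    """Percent change of pupil diameter relative to a per-subject baseline.

    ``values[t] = 100 * (X_t - baseline) / baseline``; negative values mean
    constriction relative to baseline.
    """

    values: np.ndarray
    rate: float
    baseline: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("percent-change series must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def to_diameter(self) -> np.ndarray:
        """Invert the percent-change map back to device units."""
        return self.baseline * (1.0 + self.values / 100.0)


def read_pupil_csv(path, time_col: str = "time_s",
                   diameter_col: str = "diameter",
                   fs_nominal: float = 240.0) -> RawPupilRecording:
    """Read a delimited eye-tracker export into a :class:`RawPupilRecording`.

    The file must have a header row containing ``time_col`` and
    ``diameter_col``. Sample order is preserved and no resampling occurs.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    for col in (time_col, diameter_col):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column '{col}' (found {list(df.columns)})")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return RawPupilRecording(df[time_col].to_numpy(float),
                             df[diameter_col].to_numpy(float), fs_nominal)


def write_pupil_csv(rec: RawPupilRecording, path, time_col: str = "time_s",
                    diameter_col: str = "diameter") -> None:
    pd.DataFrame({time_col: rec.time, diameter_col: rec.diameter}).to_csv(
        path, index=False)


def deblink(rec: RawPupilRecording) -> RawPupilRecording:
    """Remove blink samples (diameter == 0) by linear interpolation.

    Interior zero runs are bridged linearly between the flanking valid
    samples; zero runs touching either end are filled with the nearest valid
    value. Idempotent: a blink-free recording is returned unchanged in value.
    """
    d = rec.diameter
    valid = d > 0
    if valid.sum() < 2:
        raise DegenerateInputError("fewer than two non-blink samples")
    if valid.all():
        return rec.replace(d)
    idx = np.arange(d.size)
    filled = np.interp(idx, idx[valid], d[valid])
    return rec.replace(filled)


def hampel_window(fs: float, f0: float, coeff: float = 0.44) -> int:
    """Width of the Hampel moving window: ``coeff * fs / f0`` rounded to the
    nearest odd integer, clamped at 3 so the median stays centered."""
    if fs <= 0 or f0 <= 0:
        raise DomainError("fs and f0 must be positive")
    raw = coeff * fs / f0
    w = int(2 * np.floor(raw / 2) + 1)  # nearest odd integer, ties upward
    return max(w, 3)


def hampel_filter(rec: RawPupilRecording, window: int,
                  nsigma: float = 3.0) -> RawPupilRecording:
    """Replace moving-window median outliers beyond ``nsigma`` scaled-MAD.

    A sample is an outlier when it deviates from the window median by more
    than ``nsigma * 1.4826 * MAD``; outliers are replaced by that median.
    Window edges use scipy's reflect padding for the moving statistics.
    """
    if window % 2 == 0 or window < 3:
        raise DomainError("window must be odd and >= 3")
    d = rec.diameter
    if window > d.size:
        raise DegenerateInputError("window longer than series")
    med = median_filter(d, size=window, mode="reflect")
    mad = median_filter(np.abs(d - med), size=window, mode="reflect")
    thresh = nsigma * MAD_SCALE * mad
    out = d.copy()
    bad = np.abs(d - med) > thresh
    out[bad] = med[bad]
    return rec.replace(out)


def lowpass(rec: RawPupilRecording, f0: float = 2.0,
            order: int = 4) -> RawPupilRecording:
    """Zero-phase Butterworth low-pass at cutoff ``f0`` (forward-backward)."""
    fs = rec.fs_nominal
    if fs <= 2 * f0:
        raise DomainError(f"sampling rate {fs} too low for cutoff {f0}")
    sos = sps.butter(order, f0, btype="low", fs=fs, output="sos")
    return rec.replace(sps.sosfiltfilt(sos, rec.diameter))


def compute_baseline(rec: RawPupilRecording,
                     baseline_window: float = 60.0) -> float:
    """Maximum diameter attained over the first ``baseline_window`` seconds.

    If the recording is shorter than the window, the full span is used and a
    warning is logged.
    """
    if len(rec) == 0:
        raise EmptyInputError("empty recording")
    if rec.duration < baseline_window:
        log.warning("recording spans %.1f s < baseline window %.1f s; "
                    "using full span", rec.duration, baseline_window)
        warnings.warn("recording shorter than baseline window; using full "
                      "span", stacklevel=2)
    mask = rec.time <= rec.time[0] + baseline_window
    return float(rec.diameter[mask].max())


def percent_change(rec: RawPupilRecording,
                   baseline: float) -> PercentChangeSeries:
    """Elementwise ``100 * (X_t - baseline) / baseline``."""
    if baseline <= 0:
        raise DomainError("baseline must be positive")
    vals = 100.0 * (rec.diameter - baseline) / baseline
    return PercentChangeSeries(vals, rec.fs_nominal, baseline)


def resample_spline(series: PercentChangeSeries,
                    target_rate: float = 5.0) -> PercentChangeSeries:
    """Compress to a uniform grid at ``target_rate`` via cubic spline."""
    n = len(series)
    if n < 4:
        raise DegenerateInputError("need at least 4 samples for a cubic spline")
    t = series.time
    spline = CubicSpline(t, series.values)
    n_out = int(np.floor(t[-1] * target_rate)) + 1
    t_new = np.arange(n_out) / target_rate
    return PercentChangeSeries(spline(t_new), target_rate, series.baseline)


def preprocess(rec: RawPupilRecording,
               config: PreprocessConfig | None = None,
               return_stages: bool = False):
    """Full preprocessing chain: deblink -> Hampel -> low-pass -> baseline ->
    percent change -> spline compression.

    Returns the compressed :class:`PercentChangeSeries`; with
    ``return_stages=True`` also a dict of intermediate stages for inspection.
    """
    cfg = config or PreprocessConfig()
    stages: dict = {}
    deblinked = deblink(rec)
    w = hampel_window(rec.fs_nominal, cfg.f0, cfg.hampel_coeff)
    despiked = hampel_filter(deblinked, w, cfg.nsigma)
    filtered = lowpass(despiked, cfg.f0)
    baseline = compute_baseline(filtered, cfg.baseline_window)
    pct = percent_change(filtered, baseline)
    out = resample_spline(pct, cfg.target_rate)
    if return_stages:
        stages.update(deblinked=deblinked, despiked=despiked,
                      filtered=filtered, baseline=baseline, pct=pct,
                      hampel_window=w)
        return out, stages
    return out
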