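"""Quantification of raw triaxial water-surface displacement.

A floating triaxial sensor reports signed displacement along X/Y (horizontal)
and Z (vertical) at 10 Hz.  Feeding intensity is proxied by the per-sample
triaxial magnitude sum ``s_i = |x_i| + |y_i| + |z_i|`` accumulated over 5-s
analysis windows.  An amplitude gate calibrated to aeration-bubble noise
zeroes sub-threshold samples before summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional
import warnings

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import TrialConfig

__all__ = [
    "TriaxialTrace",
    "FilterConfig",
    "WindowSeries",
    "CorrelationTriple",
    "ZScoreStats",
    "SignalQualityError",
    "amplitude_filter",
    "triaxial_sum",
    "window_sums",
    "interaxis_correlation",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
]

SAMPLING_RATE_HZ = 10.0
WINDOW_SAMPLES = 50  # 5 s at 10 Hz


class SignalQualityError(ValueError):
    """Raised for non-finite samples, degenerate axes or malformed traces."""


@dataclass
class FilterConfig:
    """Amplitude gate for bubble/flow noise.

    ``threshold_um`` is the sensor-scale default (0.5 mm).  Synthetic
    traces calibrated to the printed window-sum regressions live at a ~1000x
    smaller per-sample scale; use :attr:`GeneratorParams.gate_um` for those.
    """

    threshold_um: float = 500.0

    def __post_init__(self) -> None:
        if self.threshold_um < 0:
            raise ValueError("amplitude threshold must be >= 0")


@dataclass
class TriaxialTrace:
    """One trial's 10 Hz per-axis displacement series (μm, signed)."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float = SAMPLING_RATE_HZ
    meta: Optional["TrialConfig"] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise SignalQualityError("axis series lengths differ")
        if self.fs <= 0:
            raise SignalQualityError("sampling rate must be positive")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise SignalQualityError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def axes(self) -> np.ndarray:
        """Stack axes into an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class WindowSeries:
    """Windowed intensity: per-window summed displacement and max wave height."""

    window_len: int
    d_sum: np.ndarray
    h_max: np.ndarray
    window_start_times: np.ndarray

    def __post_init__(self) -> None:
        self.d_sum = np.asarray(self.d_sum, dtype=float)
        self.h_max = np.asarray(self.h_max, dtype=float)
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        if not (len(self.d_sum) == len(self.h_max) == len(self.window_start_times)):
            raise ValueError("window series fields must have equal length")

    def __len__(self) -> int:
        return len(self.d_sum)


@dataclass(frozen=True)
class CorrelationTriple:
    rho_xy: float
    rho_xz: float
    rho_yz: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rho_xy, self.rho_xz, self.rho_yz)


def amplitude_filter(series: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Zero samples whose magnitude falls below the gate threshold.

    Keeps ``series[i]`` where ``|series[i]| >= threshold``, else 0; the
    pass-band is untouched, so the gate is idempotent.
    """
    arr = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise SignalQualityError("non-finite sample in displacement series")
    out = np.where(np.abs(arr) >= cfg.threshold_um, arr, 0.0)
    return out


def triaxial_sum(trace: TriaxialTrace, cfg: FilterConfig) -> np.ndarray:
    """Per-sample gated magnitude sum ``s_i = |x~_i| + |y~_i| + |z~_i|``.

    Each axis is amplitude-filtered before rectification and summation.
    """
    xs = amplitude_filter(trace.x, cfg)
    ys = amplitude_filter(trace.y, cfg)
    zs = amplitude_filter(trace.z, cfg)
    return np.abs(xs) + np.abs(ys) + np.abs(zs)


def window_sums(
    s: np.ndarray,
    window_len: int = WINDOW_SAMPLES,
    fs: float = SAMPLING_RATE_HZ,
) -> WindowSeries:
    """Aggregate a per-sample sum series into non-overlapping windows.

    Returns per-window sums (D_sum) and the per-window maximum per-sample
    triaxial sum (max wave height).  Incomplete trailing samples are dropped.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    s = np.asarray(s, dtype=float)
    n_win = len(s) // window_len
    if n_win == 0:
        warnings.warn("series shorter than one window; empty WindowSeries", stacklevel=2)
        empty = np.empty(0)
        return WindowSeries(window_len, empty.copy(), empty.copy(), empty.copy())
    trimmed = s[: n_win * window_len].reshape(n_win, window_len)
    d_sum = trimmed.sum(axis=1)
    h_max = trimmed.max(axis=1)
    starts = np.arange(n_win) * window_len / fs
    return WindowSeries(window_len, d_sum, h_max, starts)


def interaxis_correlation(trace: TriaxialTrace) -> CorrelationTriple:
    """Pairwise Pearson correlations between the raw per-axis series."""
    if len(trace) < 3:
        raise SignalQualityError("need at least 3 samples for correlation")
    axes = trace.axes()
    if np.any(np.std(axes, axis=0) == 0):
        raise SignalQualityError("zero-variance axis: correlation undefined")
    r = np.corrcoef(axes, rowvar=False)
    return CorrelationTriple(float(r[0, 1]), float(r[0, 2]), float(r[1, 2]))


# ---------------------------------------------------------------------------
# z-score normalization (sample-sd convention, ddof=1)

@dataclass
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 1


def zscore_fit(features: np.ndarray, ddof: int = 1) -> ZScoreStats:
    """Fit per-feature mean/sd on a (training) matrix.

    Uses the sample (n-1) standard deviation; a zero-sd feature is rejected
    rather than silently divided through.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    bad = np.nonzero(sd <= 0)[0]
    if bad.size:
        raise SignalQualityError(f"degenerate (zero-sd) feature columns: {bad.tolist()}")
    return ZScoreStats(mean, sd, ddof)


def zscore_apply(features: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    return (np.asarray(features, dtype=float) - stats.mean) / stats.sd


def zscore_invert(normalized: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    return np.asarray(normalized, dtype=float) * stats.sd + stats.mean


def zscore_fit_apply(features: np.ndarray, stats: ZScoreStats | None = None):
    """Normalize a matrix, fitting stats if absent. Returns (out, stats)."""
    if stats is None:
        stats = zscore_fit(features)
    return zscore_apply(features, stats), stats
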