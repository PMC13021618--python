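"""Parametric analyses of windowed feeding-intensity signals.

Peak extraction, linear response fits against culture factors, percent
increases between factor levels, peak timing, and a mean-crossing estimate of
fluctuation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_processing import WindowSeries

__all__ = [
    "LinearFit",
    "peak_displacement",
    "peak_time",
    "fit_line",
    "percent_increase",
    "zero_crossing_frequency",
    "active_segment",
]


@dataclass(frozen=True)
class LinearFit:
    """Equal-weight OLS line with intercept: y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def peak_displacement(ws: WindowSeries) -> tuple[float, int]:
    """Maximum window sum and its window index (earliest window on ties)."""
    if len(ws) == 0:
        raise ValueError("empty window series")
    idx = int(np.argmax(ws.d_sum))  # argmax returns the first maximum
    return float(ws.d_sum[idx]), idx


def peak_time(ws: WindowSeries) -> float:
    """Midpoint time (s) of the peak window."""
    _, idx = peak_displacement(ws)
    half = ws.window_len / 2.0
    # start times are on a uniform grid; infer fs from spacing when possible
    if len(ws) > 1:
        dt_win = ws.window_start_times[1] - ws.window_start_times[0]
        half_s = dt_win / 2.0
    else:
        half_s = half / 10.0  # single window: assume 10 Hz sampling
    return float(ws.window_start_times[idx] + half_s)


def fit_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Closed-form equal-weight OLS of responses on factor levels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need n >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical: slope undefined")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearFit(slope, intercept, r2, len(x))


def percent_increase(reference: float, value: float) -> float:
    """100 * (value - reference) / reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (value - reference) / reference


def zero_crossing_frequency(s: np.ndarray, fs: float) -> float:
    """Mean-crossing rate (Hz) of a series.

    The series mean is removed, sign changes are counted (zero samples attach
    to the previous sign), and the count is converted to a frequency via
    ``c / (2 T)`` with ``T`` the series duration.  A constant series has no
    crossings and returns 0 Hz.
    """
    s = np.asarray(s, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    centered = s - s.mean()
    signs = np.sign(centered)
    # zeros inherit the previous sign so a touch does not count twice
    for i in range(len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1] if i > 0 else 1.0
    crossings = int(np.count_nonzero(signs[1:] != signs[:-1]))
    duration = len(s) / fs
    return crossings / (2.0 * duration)


def active_segment(s: np.ndarray, fraction_of_max: float = 0.5) -> np.ndarray:
    """Contiguous portion of a burst where the signal exceeds a max fraction.

    Burst trials spend long stretches near zero; restricting frequency
    estimation to the active segment removes the dead time that would
    otherwise dilute the mean-crossing rate.
    """
    s = np.asarray(s, dtype=float)
    thresh = fraction_of_max * s.max()
    idx = np.nonzero(s >= thresh)[0]
    if idx.size == 0:
        return s
    return s[idx[0] : idx[-1] + 1]
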