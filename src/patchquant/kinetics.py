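"""Assembly/disassembly rates from aligned patch curves, and growth rates.

The mean aligned curve is split at its peak into an assembly and a
disassembly phase (using a 10 %-of-peak floor to exclude baseline noise),
and a straight line is fitted inside the most linear fixed-duration window
(default 3.7 s) of each phase — "most linear" meaning minimum RMS residual
of the within-window least-squares line.  Replicate rates (one per movie)
are averaged per strain.  Liquid-culture growth rates come from the slope
of log2(OD) against time over the first eight measurements (log phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignedCurve
from .errors import DegenerateCurveError, InsufficientSpanError

__all__ = [
    "LinearRegionFit",
    "RateSummary",
    "PhaseSplit",
    "split_phases",
    "find_linear_region",
    "summarize_rates",
    "growth_rate",
    "rates_from_curve",
]


@dataclass
class LinearRegionFit:
    """Best-fit line inside the most linear window of one phase."""

    phase: str  # "assembly" or "disassembly"
    window_start: float  # s
    window_duration: float  # s
    slope: float  # molecules (or ADU) per second
    intercept: float
    rms_residual: float


@dataclass
class RateSummary:
    """Per-strain aggregate of replicate rates (one rate per movie)."""

    strain: str
    phase: str
    rates: np.ndarray
    mean: float
    sd: float  # NaN for a single replicate
    n_replicates: int


@dataclass
class PhaseSplit:
    """Assembly and disassembly spans of an aligned curve.

    Each span is a ``(time, values)`` pair; the disassembly span may be
    empty (monotone rising curve), flagged by ``has_disassembly``.
    """

    assembly_time: np.ndarray
    assembly_values: np.ndarray
    disassembly_time: np.ndarray
    disassembly_values: np.ndarray
    peak_time: float

    @property
    def has_disassembly(self) -> bool:
        return len(self.disassembly_time) > 1


def split_phases(curve: AlignedCurve, floor_fraction: float = 0.1) -> PhaseSplit:
    """Split an aligned curve into assembly and disassembly phases.

    The peak is located on a 3-point moving average of the mean curve to
    resist noise; the assembly span runs from the first grid point whose
    mean exceeds ``floor_fraction`` of the peak up to the peak, the
    disassembly span from the peak to the last point above the floor.
    """
    finite = np.isfinite(curve.mean)
    t = curve.time[finite]
    v = curve.mean[finite]
    if len(v) < 3 or np.nanmax(v) <= 0:
        raise DegenerateCurveError("curve has no usable signal")
    # 3-point moving average with proper edge normalization (a plain
    # 'same' convolution dips at the ends and can fake a peak shift)
    smooth = np.convolve(v, np.ones(3), mode="same") / np.convolve(
        np.ones_like(v), np.ones(3), mode="same"
    )
    peak_idx = int(np.argmax(smooth))
    peak_val = smooth[peak_idx]
    floor = floor_fraction * peak_val
    above = np.nonzero(v > floor)[0]
    if len(above) == 0:
        raise DegenerateCurveError("no point above the phase floor")
    start = above[0]
    end = above[-1]
    if peak_idx < start:
        peak_idx = start
    if peak_idx > end:
        peak_idx = end
    return PhaseSplit(
        assembly_time=t[start : peak_idx + 1],
        assembly_values=v[start : peak_idx + 1],
        disassembly_time=t[peak_idx : end + 1],
        disassembly_values=v[peak_idx : end + 1],
        peak_time=float(t[peak_idx]),
    )


def find_linear_region(
    time: np.ndarray,
    values: np.ndarray,
    window_duration: float = 3.7,
    phase: str = "assembly",
) -> LinearRegionFit:
    """Best-fit line in the most linear fixed-duration window of a segment.

    Slides a window of ``window_duration`` across the segment at grid
    resolution, fits an ordinary least-squares line at every position, and
    returns the window with the smallest RMS residual (ties broken toward
    the earliest window).  All windows are evaluated with closed-form
    running sums, so the result is exactly the exhaustive enumeration.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time) != len(values):
        raise ValueError("time and values must have equal length")
    step = float(np.median(np.diff(time))) if len(time) > 1 else np.inf
    n_win = int(round(window_duration / step)) + 1
    if len(time) < n_win or n_win < 3:
        raise InsufficientSpanError(
            f"segment of {len(time)} points cannot hold a {window_duration} s window"
        )

    # running sums over every window of n_win consecutive samples
    def windowed_sums(a):
        c = np.concatenate([[0.0], np.cumsum(a)])
        return c[n_win:] - c[:-n_win]

    x, y = time, values
    S1, S2 = windowed_sums(x), windowed_sums(x * x)
    T0, T1 = windowed_sums(y), windowed_sums(x * y)
    Q = windowed_sums(y * y)
    n = float(n_win)
    denom = n * S2 - S1**2
    slope = (n * T1 - S1 * T0) / denom
    intercept = (T0 - slope * S1) / n
    rss = np.clip(Q - intercept * T0 - slope * T1, 0.0, None)
    rms = np.sqrt(rss / n)
    # earliest window among numerical ties: the closed-form rss cancels
    # catastrophically on near-perfect fits, so exact argmin would break
    # the earliest-window convention by ~1e-14 rounding noise
    tie_tol = 1e-8 * float(np.sqrt(np.max(Q) / n)) + 1e-12
    best = int(np.argmax(rms <= rms.min() + tie_tol))
    return LinearRegionFit(
        phase=phase,
        window_start=float(x[best]),
        window_duration=float(x[best + n_win - 1] - x[best]),
        slope=float(slope[best]),
        intercept=float(intercept[best]),
        rms_residual=float(rms[best]),
    )


def rates_from_curve(curve: AlignedCurve, window_duration: float = 3.7):
    """Assembly and disassembly linear-region fits of one aligned curve.

    Returns ``(assembly_fit, disassembly_fit)``; the disassembly fit is
    None when the curve has no falling phase.
    """
    phases = split_phases(curve)
    asm = find_linear_region(phases.assembly_time, phases.assembly_values,
                             window_duration, phase="assembly")
    dis = None
    if phases.has_disassembly:
        try:
            dis = find_linear_region(phases.disassembly_time, phases.disassembly_values,
                                     window_duration, phase="disassembly")
        except InsufficientSpanError:
            dis = None
    return asm, dis


def summarize_rates(fits: Sequence[LinearRegionFit], strain: str = "") -> RateSummary:
    """Mean and sample SD of replicate rates (one fit per averaged curve)."""
    if len(fits) < 1:
        raise ValueError("need at least one replicate fit")
    phases = {f.phase for f in fits}
    if len(phases) > 1:
        raise ValueError(f"mixed phases in one summary: {sorted(phases)}")
    rates = np.array([f.slope for f in fits], dtype=float)
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else float("nan")
    return RateSummary(
        strain=strain, phase=phases.pop(), rates=rates,
        mean=float(rates.mean()), sd=sd, n_replicates=len(rates),
    )


def growth_rate(series: pd.DataFrame, n_points: int = 8) -> float:
    """Liquid-culture growth rate in doublings per hour.

    Least-squares slope of log2(OD) versus time over the first ``n_points``
    measurements, which are taken to be the log phase.
    """
    df = series.sort_values("time").head(n_points)
    if len(df) < n_points:
        raise ValueError(f"need at least {n_points} measurements")
    od = df["od"].to_numpy(dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    t = df["time"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("time points must not be identical")
    return float(stats.linregress(t, np.log2(od)).slope)
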