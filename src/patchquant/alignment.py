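"""Temporal super-resolution realignment of single-patch intensity traces.

Individual endocytic events vary in when they start within a 1-s frame, so
naively averaging frame-indexed traces blurs the mean time course.  Here
each track receives a continuous time offset, estimated iteratively:

1. initialize every offset so the track's intensity peak sits at t = 0;
2. build the reference curve as the offset-corrected mean on a sub-frame
   grid (linear interpolation between samples);
3. re-estimate each track's offset by minimizing its mean squared
   difference to the reference over a bounded continuous search
   (coarse scan ± two frame intervals, then scalar minimization);
4. repeat 2–3 until the largest offset change drops below a tolerance.

Only time offsets are fitted — amplitudes are averaged raw, so the mean
curve stays in integrated-density (or molecule) units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .calibration import CalibrationCurve
from .errors import AlignmentWarning, CalibrationError, InsufficientDataError

__all__ = ["AlignedCurve", "align_tracks", "curve_to_molecules"]


@dataclass
class AlignedCurve:
    """Mean ± SD intensity versus continuous time for many aligned tracks.

    ``mean``/``sd`` are NaN wherever fewer than ``min_tracks`` (3) tracks
    contribute; ``n`` counts contributing tracks per grid point.
    ``offsets[i]`` is subtracted from track i's times to place it on the
    common axis.
    """

    time: np.ndarray  # s, sub-frame grid
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    offsets: np.ndarray
    units: str = "ADU"
    n_iter: int = 0
    converged: bool = True
    sse_history: tuple = ()  # total squared deviation after each iteration

    @property
    def n_tracks(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def _interp_track(times, values, grid, offset):
    """Track values on the common grid after removing its offset; NaN outside."""
    shifted = times - offset
    out = np.interp(grid, shifted, values, left=np.nan, right=np.nan)
    return out


def align_tracks(
    tracks: Sequence,
    grid_step: float = 0.1,
    tol: float = 0.01,
    max_iter: int = 50,
    search_halfwidth: Optional[float] = None,
    min_tracks: int = 3,
) -> AlignedCurve:
    """Align patch intensity traces with continuous time offsets and average.

    ``tracks`` may be :class:`~patchquant.tracking.PatchTrack` objects or
    ``(times, values)`` pairs.  ``grid_step`` must not exceed the frame
    interval; the offset search is bounded to ± two frame intervals around
    the current estimate per iteration (``search_halfwidth`` overrides).

    Emits :class:`AlignmentWarning` if the offsets are still moving by more
    than ``tol`` seconds after ``max_iter`` iterations.
    """
    data = []
    for tr in tracks:
        if hasattr(tr, "times"):
            data.append((np.asarray(tr.times, float), np.asarray(tr.intensity, float)))
        else:
            t, v = tr
            data.append((np.asarray(t, float), np.asarray(v, float)))
    if len(data) < min_tracks:
        raise InsufficientDataError(f"need at least {min_tracks} accepted tracks")

    frame_interval = float(np.median(np.concatenate([np.diff(t) for t, _ in data])))
    if grid_step > frame_interval + 1e-12:
        raise ValueError("grid_step must not exceed the frame interval")
    if search_halfwidth is None:
        search_halfwidth = 2.0 * frame_interval

    # 1. peak initialization
    offsets = np.array([t[int(np.argmax(v))] for t, v in data], dtype=float)

    lo = min(t[0] - o for (t, _), o in zip(data, offsets)) - search_halfwidth
    hi = max(t[-1] - o for (t, _), o in zip(data, offsets)) + search_halfwidth
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    converged = False
    it = 0
    sse_history = []
    for it in range(1, max_iter + 1):
        # 2. reference = offset-corrected mean
        stack = np.vstack([_interp_track(t, v, grid, o) for (t, v), o in zip(data, offsets)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmean(stack, axis=0)
        valid = np.isfinite(ref)
        ref_t, ref_v = grid[valid], ref[valid]

        # 3. per-track continuous offset against the reference
        new_offsets = offsets.copy()
        for i, (t, v) in enumerate(data):
            def mse(o, t=t, v=v):
                pred = np.interp(t - o, ref_t, ref_v, left=np.nan, right=np.nan)
                good = np.isfinite(pred)
                if good.sum() < 3:
                    return np.inf
                return float(np.mean((v[good] - pred[good]) ** 2))

            a, b = offsets[i] - search_halfwidth, offsets[i] + search_halfwidth
            coarse = np.linspace(a, b, 41)
            best = coarse[int(np.argmin([mse(o) for o in coarse]))]
            span = (coarse[1] - coarse[0])
            res = minimize_scalar(mse, bounds=(best - span, best + span), method="bounded",
                                  options={"xatol": min(tol / 10, 1e-3)})
            new_offsets[i] = res.x if np.isfinite(res.fun) else offsets[i]

        # pin the translation gauge: keep the mean offset fixed
        new_offsets -= new_offsets.mean() - offsets.mean()
        delta = float(np.max(np.abs(new_offsets - offsets)))
        sse = 0.0
        for (t, v), o in zip(data, new_offsets):
            pred = np.interp(t - o, ref_t, ref_v, left=np.nan, right=np.nan)
            good = np.isfinite(pred)
            sse += float(np.sum((v[good] - pred[good]) ** 2))
        sse_history.append(sse)
        offsets = new_offsets
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"offset change still {delta:.3g} s after {max_iter} iterations",
            AlignmentWarning,
        )

    stack = np.vstack([_interp_track(t, v, grid, o) for (t, v), o in zip(data, offsets)])
    n = np.isfinite(stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    low = n < min_tracks
    mean[low] = np.nan
    sd[low] = np.nan

    keep = n >= 1
    return AlignedCurve(
        time=grid[keep], mean=mean[keep], sd=sd[keep], n=n[keep],
        offsets=offsets, n_iter=it, converged=converged,
        sse_history=tuple(sse_history),
    )


def curve_to_molecules(curve: AlignedCurve, cal: CalibrationCurve) -> AlignedCurve:
    """Convert an aligned curve from ADU to molecules via the calibration slope.

    Patch integrated densities are already locally background subtracted,
    so only the slope applies (no intercept).
    """
    if cal.slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return replace(
        curve,
        mean=curve.mean / cal.slope,
        sd=curve.sd / cal.slope,
        units="molecules",
    )
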