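"""End-to-end analysis of one time-lapse movie.

Chains the whole method: flat-field/dark correction → illumination-based
crop → automatic photobleaching correction → patch detection, linking and
screening → temporal super-resolution realignment → conversion to
molecules → most-linear-window rate fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import alignment, corrections, kinetics, photobleach, tracking
from .calibration import CalibrationCurve
from .core import MovieStack

__all__ = ["MovieAnalysis", "process_movie"]


@dataclass
class MovieAnalysis:
    """Everything the pipeline produced for one movie."""

    corrected: MovieStack
    illumination: corrections.Gaussian2DModel
    bleach_report: dict
    tracks: list
    curve: alignment.AlignedCurve
    assembly: Optional[kinetics.LinearRegionFit]
    disassembly: Optional[kinetics.LinearRegionFit]


def process_movie(
    stack: MovieStack,
    dark: np.ndarray,
    flat: np.ndarray,
    min_illum_fraction: float = 0.5,
    detect_sigma: float = 1.5,
    min_prominence: Optional[float] = None,
    calibration: Optional[CalibrationCurve] = None,
    grid_step: float = 0.1,
    window_duration: float = 3.7,
    screen_kw: Optional[dict] = None,
) -> MovieAnalysis:
    """Run the full pipeline on a raw movie; see the module docstring.

    With ``calibration`` the aligned curve and rates are in molecules (per
    second); otherwise they stay in integrated-density ADU.
    """
    corrected = corrections.correct_stack(stack, dark, flat)
    illum_model = corrections.fit_illumination(np.asarray(flat, float) - np.asarray(dark, float))
    cropped = corrections.crop_poorly_illuminated(corrected, illum_model, min_illum_fraction)
    bleached, report = photobleach.bleach_correct(cropped)
    tracks = tracking.track_movie(
        bleached, sigma=detect_sigma, min_prominence=min_prominence, **(screen_kw or {})
    )
    curve = alignment.align_tracks(tracks, grid_step=grid_step)
    if calibration is not None:
        curve = alignment.curve_to_molecules(curve, calibration)
    assembly, disassembly = kinetics.rates_from_curve(curve, window_duration)
    return MovieAnalysis(
        corrected=bleached,
        illumination=illum_model,
        bleach_report=report,
        tracks=tracks,
        curve=curve,
        assembly=assembly,
        disassembly=disassembly,
    )
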