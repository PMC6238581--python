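"""Fluorescence-to-molecule-count calibration.

Strains expressing different GFP-tagged proteins at known copy numbers
(from quantitative immunoblotting) are imaged under identical settings.
Cells are segmented on the Z-sum projection, their background-corrected
total fluorescence is measured, autofluorescence (measured in a
nonfluorescent control strain) is subtracted, and the per-strain mean
intensities are regressed on the known molecules per cell.  The slope of
that line converts any background-corrected integrated intensity — a whole
cell or a single endocytic patch — into a number of molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import filters, measure, morphology, segmentation

from .core import MovieStack
from .errors import (
    CalibrationError,
    ConfigurationError,
    DimensionError,
    InsufficientDataError,
    SegmentationError,
)

__all__ = [
    "CalibrationCurve",
    "segment_cells",
    "measure_cells",
    "subtract_autofluorescence",
    "fit_calibration",
    "to_molecules",
    "measure_strain_stack",
]


@dataclass
class CalibrationCurve:
    """Linear map from background-corrected intensity (ADU) to molecules.

    ``slope`` is ADU per molecule.  ``per_strain`` holds one row per
    calibration strain (strain, mean_intensity, known_molecules), matching
    the one-point-per-strain construction of the curve.
    """

    slope: float
    intercept: float
    r_squared: float
    per_strain: Optional[pd.DataFrame] = None
    through_origin: bool = False

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "through_origin": self.through_origin,
        }
        if self.per_strain is not None:
            payload["per_strain"] = self.per_strain.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        per_strain = payload.get("per_strain")
        return cls(
            slope=payload["slope"],
            intercept=payload["intercept"],
            r_squared=payload["r_squared"],
            per_strain=pd.DataFrame(per_strain) if per_strain is not None else None,
            through_origin=payload.get("through_origin", False),
        )


def segment_cells(
    projection: np.ndarray,
    min_area: int = 500,
    max_area: int = 5000,
    discard_border: bool = True,
) -> np.ndarray:
    """Label individual cells in a corrected sum-projection image.

    Otsu threshold → fill holes → distance-transform watershed to split
    touching cells → drop regions outside ``[min_area, max_area]`` pixels
    or touching the image border.  Area bounds default to the plausible
    single-cell range at the synthetic pixel scale.

    Returns an integer label image; raises :class:`SegmentationError` if no
    region survives.
    """
    projection = np.asarray(projection, dtype=float)
    if np.ptp(projection) <= 0:
        raise SegmentationError("blank image: nothing to segment")
    thresh = filters.threshold_otsu(projection)
    binary = ndi.binary_fill_holes(projection > thresh)
    if not binary.any():
        raise SegmentationError("threshold produced an empty foreground")

    # smoothed EDT + h-maxima markers: one marker per cell even for
    # elongated (rod-shaped) cells, whose raw distance ridge carries many
    # shallow discretization maxima; touching cells sit across a saddle
    # deeper than h and are still split
    distance = ndi.gaussian_filter(ndi.distance_transform_edt(binary), 2.0)
    markers = measure.label(morphology.h_maxima(distance, 2.0))
    if markers.max() == 0:
        labels = measure.label(binary)
    else:
        labels = segmentation.watershed(-distance, markers, mask=binary)

    if discard_border:
        labels = segmentation.clear_border(labels)
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        raise SegmentationError("no region within the configured area bounds")
    return out


def _modal_background(values: np.ndarray) -> float:
    """Modal pixel value, from the peak of a Freedman–Diaconis histogram."""
    values = np.asarray(values, dtype=float).ravel()
    if len(values) == 0:
        return 0.0
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) / max(len(values), 1) ** (1 / 3)
    if width <= 0:
        return float(np.median(values))
    n_bins = max(int(np.ceil(np.ptp(values) / width)), 8)
    counts, edges = np.histogram(values, bins=n_bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def measure_cells(
    labels: np.ndarray,
    projection: np.ndarray,
    strain: str = "",
    dilate: float = 4.0,
) -> pd.DataFrame:
    """Background-corrected total fluorescence of each labelled cell.

    Footprints are expanded ``dilate`` pixels into the background (never
    into a neighbouring cell) before integrating, so the optical halo that
    the point-spread function pushes past the threshold boundary is
    counted — without expansion, a fixed fraction of every cell's signal
    is lost and the calibration slope is biased low.  The integrated
    intensity is then reduced by the modal pixel value of the non-cell
    region times the footprint area.  Returns one row per cell:
    ``cell_id, strain, total_fluorescence, area, y, x``.
    """
    labels = np.asarray(labels)
    projection = np.asarray(projection, dtype=float)
    if labels.shape != projection.shape:
        raise DimensionError("labels and projection must share a shape")
    if dilate > 0:
        labels = segmentation.expand_labels(labels, distance=dilate)
    background = _modal_background(projection[labels == 0])
    rows = []
    for region in measure.regionprops(labels, intensity_image=projection):
        total = float(region.image_intensity[region.image].sum()) - background * region.area
        cy, cx = region.centroid
        rows.append(
            {"cell_id": region.label, "strain": strain,
             "total_fluorescence": max(total, 0.0), "area": int(region.area),
             "y": cy, "x": cx}
        )
    return pd.DataFrame(rows, columns=["cell_id", "strain", "total_fluorescence", "area", "y", "x"])


def subtract_autofluorescence(measurements: pd.DataFrame, control_mean: float) -> pd.DataFrame:
    """Subtract the nonfluorescent-strain mean from every cell total.

    Negative corrected totals are clipped to zero and flagged in a
    ``clipped`` column.
    """
    if control_mean is None or not np.isfinite(control_mean):
        raise ConfigurationError("control_mean from the nonfluorescent strain is required")
    out = measurements.copy()
    corrected = out["total_fluorescence"] - control_mean
    out["clipped"] = corrected < 0
    out["total_fluorescence"] = corrected.clip(lower=0.0)
    return out


def fit_calibration(per_strain: pd.DataFrame, through_origin: bool = False) -> CalibrationCurve:
    """Ordinary least-squares line of mean intensity on known molecules.

    ``per_strain`` needs columns ``strain``, ``mean_intensity`` and
    ``known_molecules``, one row per strain (strain means, not pooled
    single cells).  With ``through_origin=True`` the intercept is fixed at
    zero, appropriate when autofluorescence has already been subtracted.
    """
    required = {"strain", "mean_intensity", "known_molecules"}
    if not required <= set(per_strain.columns):
        raise ValueError(f"per_strain must have columns {sorted(required)}")
    if per_strain["known_molecules"].nunique() < 3:
        raise InsufficientDataError(
            "need at least 3 strains with distinct known molecule counts"
        )
    x = per_strain["known_molecules"].to_numpy(dtype=float)
    y = per_strain["mean_intensity"].to_numpy(dtype=float)
    if through_origin:
        slope = float((x @ y) / (x @ x))
        intercept = 0.0
        ss_res = float(((y - slope * x) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    if slope <= 0:
        raise CalibrationError("fitted calibration slope is non-positive")
    return CalibrationCurve(
        slope=slope, intercept=intercept, r_squared=max(min(r2, 1.0), 0.0),
        per_strain=per_strain.reset_index(drop=True), through_origin=through_origin,
    )


def to_molecules(intensity, curve: CalibrationCurve):
    """Convert background-corrected intensity (ADU) to molecules.

    ``(intensity - intercept) / slope``; results may be fractional and may
    be negative for intensities below the intercept (the caller decides how
    to treat those).
    """
    if curve.slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return (np.asarray(intensity, dtype=float) - curve.intercept) / curve.slope


def correct_and_project(stack: MovieStack, dark: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Z-sum projection of a raw stack, corrected at the projection level.

    Summing the raw Z-sections first and then dark-subtracting and
    flat-fielding the single projected frame (with ``n_z * dark``) is
    algebraically the same linear correction, but the clip at zero then
    acts on the projection, where the noise floor is far below any real
    signal.  Correcting section-by-section clips inside dim cells — each
    section of a weakly expressing strain sits near the read noise — and
    inflates their totals, bending the calibration line.
    """
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if dark.shape != flat.shape or dark.shape != stack.data.shape[-2:]:
        raise DimensionError("dark/flat must match the stack frame shape")
    flat_d = flat - dark
    if np.any(flat_d <= 0):
        from .errors import FlaggedPixelError

        raise FlaggedPixelError(
            "flat-field has non-positive pixels after dark subtraction",
            pixels=np.argwhere(flat_d <= 0),
        )
    # no zero-clip here: clipping puts a half-normal pedestal on the
    # near-zero halo pixels inside the measurement band, which biases dim
    # strains upward and bends the calibration line
    projection = stack.sum_projection()[0] - stack.n_z * dark
    return projection / (flat_d / flat_d.max())


def measure_strain_stack(stack: MovieStack, strain: str = "", **segment_kw) -> pd.DataFrame:
    """Segment and measure all cells of a single-time-point calibration stack."""
    projection = stack.sum_projection()[0]
    labels = segment_cells(projection, **segment_kw)
    return measure_cells(labels, projection, strain=strain)
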