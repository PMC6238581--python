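"""Camera-noise / uneven-illumination correction and automatic cropping.

Frames are corrected by dark-frame subtraction and division by the
normalized flat field.  The flat field is then summarized by a best-fit
axis-aligned elliptical 2-D Gaussian, and poorly illuminated areas — where
the fitted Gaussian (peak-normalized) falls below a configurable fraction —
are cropped away by taking the largest axis-aligned rectangle that stays
above the threshold, so downstream arrays remain dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import MovieStack
from .errors import DimensionError, EmptyCropError, FitError, FlaggedPixelError

__all__ = [
    "Gaussian2DModel",
    "correct_frame",
    "correct_stack",
    "fit_illumination",
    "crop_poorly_illuminated",
    "largest_true_rectangle",
]


@dataclass
class Gaussian2DModel:
    """Axis-aligned elliptical 2-D Gaussian plus constant offset.

    ``f(y, x) = amplitude * exp(-((x-cx)^2 / (2 sx^2) + (y-cy)^2 / (2 sy^2)))
    + offset``; the value at the center is ``amplitude + offset``.
    """

    amplitude: float
    center: tuple  # (x, y) px
    sigma: tuple  # (sx, sy) px
    offset: float = 0.0
    rms_residual: float = float("nan")

    def __post_init__(self):
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise ValueError("sigma components must be positive")

    def evaluate(self, shape) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.center
        sx, sy = self.sigma
        return self.amplitude * np.exp(
            -((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))
        ) + self.offset

    def normalized(self, shape) -> np.ndarray:
        """Offset-free field scaled to peak 1 (the illumination profile)."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.center
        sx, sy = self.sigma
        return np.exp(-((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2)))


def correct_frame(raw: np.ndarray, dark: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Dark-subtract and flat-field one frame: ``(raw - dark) / norm_flat``.

    ``norm_flat`` is the dark-subtracted flat scaled to maximum 1, so the
    best-illuminated pixel is unchanged.  Output is clipped below at zero.

    Raises
    ------
    DimensionError
        If the three images differ in shape.
    FlaggedPixelError
        If the dark-subtracted flat has non-positive pixels (correction is
        undefined there); carries the offending pixel coordinates.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if raw.shape[-2:] != dark.shape or dark.shape != flat.shape:
        raise DimensionError(
            f"shape mismatch: raw {raw.shape}, dark {dark.shape}, flat {flat.shape}"
        )
    flat_d = flat - dark
    bad = np.argwhere(flat_d <= 0)
    if len(bad):
        raise FlaggedPixelError(
            f"{len(bad)} flat-field pixels are <= 0 after dark subtraction", pixels=bad
        )
    norm_flat = flat_d / flat_d.max()
    return np.clip((raw - dark) / norm_flat, 0.0, None)


def correct_stack(stack: MovieStack, dark: np.ndarray, flat: np.ndarray) -> MovieStack:
    """Apply :func:`correct_frame` to every Z-section of every frame."""
    corrected = correct_frame(stack.data.reshape(-1, *stack.data.shape[-2:]), dark, flat)
    return stack.with_data(corrected.reshape(stack.data.shape), flatfield_corrected=True)


def fit_illumination(flat: np.ndarray) -> Gaussian2DModel:
    """Least-squares 2-D Gaussian fit to an illumination reference image.

    Axis-aligned elliptical Gaussian with free offset; the field falloff of
    the instrument is near-isotropic, so a rotation angle would be
    unidentifiable at low contrast and is not fitted.

    Raises
    ------
    FitError
        On a constant image (no structure to fit) or non-convergence; the
        error carries the last parameter vector.
    """
    flat = np.asarray(flat, dtype=float)
    if np.ptp(flat) <= 0:
        raise FitError("flat field has no dynamic range (constant image)")
    yy, xx = np.mgrid[0 : flat.shape[0], 0 : flat.shape[1]]

    offset0 = float(flat.min())
    amp0 = float(flat.max() - flat.min())
    w = np.clip(flat - offset0, 0, None)
    wsum = w.sum()
    cx0 = float((xx * w).sum() / wsum)
    cy0 = float((yy * w).sum() / wsum)
    sx0 = max(np.sqrt(((xx - cx0) ** 2 * w).sum() / wsum), 1.0)
    sy0 = max(np.sqrt(((yy - cy0) ** 2 * w).sum() / wsum), 1.0)
    p0 = np.array([amp0, cx0, cy0, sx0, sy0, offset0])

    def resid(p):
        amp, cx, cy, sx, sy, off = p
        model = amp * np.exp(
            -((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))
        ) + off
        return (model - flat).ravel()

    big = 10 * max(flat.shape)
    result = least_squares(
        resid, p0,
        bounds=([0, -big, -big, 1e-3, 1e-3, -np.inf], [np.inf, big, big, big, big, np.inf]),
        max_nfev=200,
    )
    if not result.success:
        raise FitError("illumination Gaussian fit did not converge", last_params=result.x)
    amp, cx, cy, sx, sy, off = result.x
    if amp <= 1e-12 * max(abs(off), 1.0):
        raise FitError("degenerate fit: amplitude ~ 0 (no illumination structure)",
                       last_params=result.x)
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return Gaussian2DModel(
        amplitude=float(amp), center=(float(cx), float(cy)),
        sigma=(float(sx), float(sy)), offset=float(off), rms_residual=rms,
    )


def largest_true_rectangle(mask: np.ndarray) -> tuple:
    """Largest axis-aligned all-True rectangle in a boolean image.

    Classic maximal-rectangle algorithm (per-row histogram of column
    heights + monotonic stack), O(Y·X).  Returns ``(y0, y1, x0, x1)`` as
    half-open slice bounds, or ``None`` if the mask is all False.
    """
    mask = np.asarray(mask, dtype=bool)
    best_area = 0
    best = None
    heights = np.zeros(mask.shape[1], dtype=int)
    for i in range(mask.shape[0]):
        heights = np.where(mask[i], heights + 1, 0)
        stack = []  # (start_col, height), heights strictly increasing
        for j in range(len(heights) + 1):
            h = int(heights[j]) if j < len(heights) else 0
            start = j
            while stack and stack[-1][1] >= h:
                s, sh = stack.pop()
                area = sh * (j - s)
                if area > best_area:
                    best_area = area
                    best = (i - sh + 1, i + 1, s, j)
                start = s
            if not stack or h > stack[-1][1]:
                stack.append((start, h))
    return best


def crop_poorly_illuminated(
    stack: MovieStack, model: Gaussian2DModel, min_fraction: float = 0.5
) -> MovieStack:
    """Crop the movie to the largest rectangle of adequate illumination.

    The fitted Gaussian (normalized to peak 1) must be at least
    ``min_fraction`` everywhere inside the returned rectangle.  The crop
    box is computed once per movie and recorded in ``meta['crop_box']`` as
    ``(y0, y1, x0, x1)`` half-open bounds.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must lie in (0, 1)")
    field = model.normalized(stack.data.shape[-2:])
    box = largest_true_rectangle(field >= min_fraction)
    if box is None:
        raise EmptyCropError("no pixel reaches the illumination threshold")
    y0, y1, x0, x1 = box
    return stack.with_data(stack.data[:, :, y0:y1, x0:x1], crop_box=[y0, y1, x0, x1])
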