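"""Automatic photobleaching correction of yeast time-lapse movies.

Median intracellular brightness decays under constant illumination.  The
correction pipeline is:

1. histogram the pixel brightness of the first (corrected, cropped)
   sum-projection frame;
2. fit the histogram with a two-term Gaussian (background + intracellular
   pixel populations) and identify the background component with a one-term
   Gaussian fit to the bins preceding the histogram peak;
3. choose the lowest brightness for which the pixels at or above it are
   predicted ≥ 95 % intracellular;
4. freeze an intracellular mask: pixels above that threshold in at least
   8 of the first 10 frames;
5. fit the per-frame median of the masked pixels with a double-exponential
   decay ``A (a1 e^{-k1 t} + a2 e^{-k2 t})``, normalized to 1 at t = 0;
6. divide every frame by the normalized decay.

The first (fast) exponential term usually tracks bleaching of cellular
autofluorescence and the second (slow) term bleaching of GFP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .core import MovieStack
from .errors import (
    CorrectionError,
    DegenerateMixtureError,
    FitError,
    MaskingError,
    ThresholdError,
)

__all__ = [
    "BrightnessHistogram",
    "PixelMixtureModel",
    "IntracellularMask",
    "BleachModel",
    "fit_pixel_mixture",
    "intracellular_threshold",
    "build_intracellular_mask",
    "fit_bleach_model",
    "apply_bleach_correction",
    "bleach_correct",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class BrightnessHistogram:
    """Pixel-brightness histogram of one frame.

    ``counts[i]`` is the number of pixels with brightness in
    ``[bin_edges[i], bin_edges[i+1])``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.bin_edges)))

    @classmethod
    def from_image(cls, image: np.ndarray) -> "BrightnessHistogram":
        """Histogram an image with Freedman–Diaconis bin width."""
        vals = np.asarray(image, dtype=float).ravel()
        q75, q25 = np.percentile(vals, [75, 25])
        width = 2.0 * (q75 - q25) / len(vals) ** (1 / 3)
        if width <= 0:
            width = max(np.ptp(vals) / 64.0, 1.0)
        n_bins = max(int(np.ceil(np.ptp(vals) / width)), 16)
        counts, edges = np.histogram(vals, bins=n_bins)
        return cls(bin_edges=edges, counts=counts)


@dataclass
class PixelMixtureModel:
    """Two-Gaussian model of the pixel-brightness histogram.

    Each component is a ``(weight, mean, sd)`` triple; weights are the
    fractions of total pixel mass.  The intracellular mean always exceeds
    the background mean.
    """

    background: tuple
    intracellular: tuple

    def __post_init__(self):
        wb, mb, sb = self.background
        wi, mi, si = self.intracellular
        if wb < 0 or wi < 0 or sb <= 0 or si <= 0:
            raise ValueError("weights must be >= 0 and sds > 0")
        if not mi > mb:
            raise ValueError("intracellular mean must exceed background mean")


@dataclass
class IntracellularMask:
    """Frozen boolean mask of intracellular pixels.

    Computed once from the first ``frames_used`` frames and reused for the
    whole movie; a pixel is included iff its brightness exceeded
    ``threshold`` in at least ``min_votes`` of those frames.
    """

    mask: np.ndarray
    threshold: float
    frames_used: int
    min_votes: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BleachModel:
    """Double-exponential photobleaching decay, normalized to 1 at t = 0.

    ``decay(t) = a1 exp(-k1 t) + a2 exp(-k2 t)`` with ``a1 + a2 = 1`` and
    the rate constants ordered ``k1 >= k2 >= 0``.  ``normalization`` is the
    fitted trace value at t = 0 in ADU (before normalizing).
    """

    a1: float
    k1: float
    a2: float = 0.0
    k2: float = 0.0
    normalization: float = 1.0

    def __post_init__(self):
        if not np.isclose(self.a1 + self.a2, 1.0, atol=1e-9):
            raise ValueError("amplitudes must sum to 1 (normalized decay)")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (self.k1 >= self.k2 >= 0):
            raise ValueError("rate constants must satisfy k1 >= k2 >= 0")

    def decay(self, t):
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.k1 * t) + self.a2 * np.exp(-self.k2 * t)

    def __call__(self, t):
        return self.decay(t)

    @classmethod
    def identity(cls) -> "BleachModel":
        """No bleaching: decay ≡ 1."""
        return cls(a1=1.0, k1=0.0, a2=0.0, k2=0.0)


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return _gauss(x, a1, m1, s1) + _gauss(x, a2, m2, s2)


def fit_pixel_mixture(hist: BrightnessHistogram) -> PixelMixtureModel:
    """Separate background and intracellular pixel populations.

    Fits a two-term Gaussian to the full histogram and a one-term Gaussian
    to the bins at or below the histogram mode; the mixture component whose
    mean lies nearer the pre-peak fit is labelled background.

    Raises
    ------
    FitError
        If either least-squares fit fails to converge.
    DegenerateMixtureError
        If the two component means are closer than a quarter of the pooled
        standard deviation (a single population: no threshold exists).
    """
    x = hist.centers
    y = hist.counts
    if np.count_nonzero(y) < 10:
        raise ValueError("histogram needs at least 10 nonempty bins")

    mode_idx = int(np.argmax(y))
    # one-term fit to the region preceding (and including) the peak
    lo = slice(0, mode_idx + 1)
    if mode_idx < 3:
        raise DegenerateMixtureError(
            "histogram mode at the lower edge: no resolvable background component"
        )
    sd0 = max(np.sqrt(np.average((x[lo] - x[mode_idx]) ** 2, weights=y[lo] + 1e-12)), hist.bin_width)
    try:
        # the background mean may not exceed the mode: fitting only the
        # rising shoulder is otherwise ill-posed (the tail of an arbitrarily
        # large Gaussian centered far to the right fits it too)
        p_bg, _ = curve_fit(
            _gauss,
            x[lo],
            y[lo],
            p0=[y[mode_idx], x[mode_idx], sd0],
            bounds=([0, x[0] - sd0, hist.bin_width / 10],
                    [np.inf, x[mode_idx] + hist.bin_width, x[-1] - x[0]]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"pre-peak background fit failed: {exc}") from exc

    # two-term fit to the full histogram, seeded by the background fit and
    # the weighted stats of the bins well above the fitted background
    above = x > p_bg[1] + 3.0 * p_bg[2]
    if above.sum() < 3 or y[above].sum() <= 0:
        above = np.arange(len(x)) > mode_idx
    w_hi = y[above] + 1e-12
    mu_hi = np.average(x[above], weights=w_hi)
    sd_hi = max(np.sqrt(np.average((x[above] - mu_hi) ** 2, weights=w_hi)), hist.bin_width)
    p0 = [p_bg[0], p_bg[1], p_bg[2], max(y[above].max(), 1.0), mu_hi, sd_hi]
    span = x[-1] - x[0]
    try:
        p2, _ = curve_fit(
            _two_gauss,
            x,
            y,
            p0=p0,
            sigma=np.sqrt(np.maximum(y, 1.0)),  # Poisson-weighted histogram fit
            bounds=([0, x[0], hist.bin_width / 10] * 2, [np.inf, x[-1], span] * 2),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"two-term histogram fit failed: {exc}", last_params=p0) from exc

    comps = [(p2[0], p2[1], p2[2]), (p2[3], p2[4], p2[5])]
    # component nearer the pre-peak fit mean is the background
    comps.sort(key=lambda c: abs(c[1] - p_bg[1]))
    (ab, mb, sb), (ai, mi, si) = comps

    pooled = np.sqrt(0.5 * (sb**2 + si**2))
    if abs(mi - mb) < pooled / 4:
        raise DegenerateMixtureError(
            f"component means {mb:.1f} and {mi:.1f} are indistinguishable "
            f"(|Δμ| < pooled sd / 4 = {pooled / 4:.1f})"
        )
    if mi < mb:  # background fit landed on the brighter mode; swap
        (ab, mb, sb), (ai, mi, si) = (ai, mi, si), (ab, mb, sb)

    # amplitude -> pixel-mass weight (area under each Gaussian)
    mass_b = ab * sb * np.sqrt(2 * np.pi)
    mass_i = ai * si * np.sqrt(2 * np.pi)
    total = mass_b + mass_i
    if min(mass_b, mass_i) < 0.02 * total:
        raise DegenerateMixtureError(
            "one mixture component carries <2% of the pixel mass: "
            "the histogram is effectively a single population"
        )
    return PixelMixtureModel(
        background=(mass_b / total, float(mb), float(sb)),
        intracellular=(mass_i / total, float(mi), float(si)),
    )


def intracellular_threshold(
    model: PixelMixtureModel,
    hist: BrightnessHistogram,
    target_fraction: float = 0.95,
) -> float:
    """Lowest bin edge above which pixels are predicted mostly intracellular.

    The purity criterion is cumulative: at candidate threshold ``t`` the
    predicted intracellular mass at or above ``t``, divided by the total
    predicted mass at or above ``t``, must reach ``target_fraction``.
    Masses come from the fitted Gaussian survival functions weighted by the
    mixture weights.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    wb, mb, sb = model.background
    wi, mi, si = model.intracellular
    edges = hist.bin_edges
    mass_bg = wb * norm.sf(edges, loc=mb, scale=sb)
    mass_in = wi * norm.sf(edges, loc=mi, scale=si)
    with np.errstate(divide="ignore", invalid="ignore"):
        purity = mass_in / (mass_in + mass_bg)
    ok = np.nonzero(purity >= target_fraction)[0]
    if len(ok) == 0:
        raise ThresholdError(
            "no bin edge reaches the requested intracellular purity "
            "(populations too overlapped)"
        )
    return float(edges[ok[0]])


def build_intracellular_mask(
    stack: MovieStack,
    threshold: float,
    frames_used: int = 10,
    min_votes: int = 8,
) -> IntracellularMask:
    """Vote a frozen intracellular mask from the first frames of a movie.

    Operates on sum projections over Z.  A pixel is intracellular iff it is
    brighter than ``threshold`` in at least ``min_votes`` of the first
    ``frames_used`` frames.
    """
    if stack.n_frames < frames_used:
        raise ValueError(
            f"movie has {stack.n_frames} frames; needs >= {frames_used}"
        )
    proj = stack.sum_projection()[:frames_used]
    votes = (proj > threshold).sum(axis=0)
    mask = votes >= min_votes
    if not mask.any():
        raise MaskingError("intracellular mask is empty at this threshold")
    return IntracellularMask(
        mask=mask, threshold=float(threshold), frames_used=frames_used, min_votes=min_votes
    )


def median_intracellular_trace(stack: MovieStack, mask: IntracellularMask) -> np.ndarray:
    """Per-frame median brightness of the masked pixels (sum projection)."""
    proj = stack.sum_projection()
    return np.median(proj[:, mask.mask], axis=1)


def _biexp(t, amp, w, k1, k2):
    return amp * (w * np.exp(-k1 * t) + (1 - w) * np.exp(-k2 * t))


def _monoexp(t, amp, k):
    return amp * np.exp(-k * t)


def fit_bleach_model(stack: MovieStack, mask: IntracellularMask) -> BleachModel:
    """Fit the double-exponential bleach decay to the median intracellular trace.

    The trace ``m(t)`` of per-frame medians is fit with
    ``A (a1 e^{-k1 t} + a2 e^{-k2 t})`` by unweighted least squares.
    Initialization is deterministic: a log-linear fit to the second half of
    the trace seeds the slow constant ``k2``; the log-linear fit to the
    positive early residual seeds ``k1``.  If the two-term fit does not
    improve the residual RMS of a single exponential by at least 1 %, the
    single-exponential fit is returned instead (as ``a2 = 0``).
    """
    if stack.n_frames < 10:
        raise ValueError("need at least 10 frames to fit a bleach model")
    if mask.n_pixels == 0:
        raise MaskingError("mask is empty")
    t = stack.times
    m = median_intracellular_trace(stack, mask)
    if np.any(m <= 0):
        raise FitError("median intracellular trace has non-positive values")

    # deterministic seeds -------------------------------------------------
    half = len(t) // 2
    tail_fit = np.polyfit(t[half:], np.log(m[half:]), 1)
    k2_0 = max(-tail_fit[0], 0.0)
    a2_0 = np.exp(tail_fit[1])
    resid = m - a2_0 * np.exp(-k2_0 * t)
    early = resid[: max(len(t) // 4, 3)]
    t_early = t[: len(early)]
    pos = early > 0
    if pos.sum() >= 2:
        head_fit = np.polyfit(t_early[pos], np.log(early[pos]), 1)
        k1_0 = max(-head_fit[0], k2_0 + 1e-3)
        a1_0 = np.exp(head_fit[1])
    else:
        k1_0, a1_0 = k2_0 + 0.05, 0.1 * a2_0
    amp0 = a1_0 + a2_0
    w0 = np.clip(a1_0 / amp0, 1e-3, 1 - 1e-3)

    # single-exponential reference ---------------------------------------
    last_params = None
    try:
        p1, _ = curve_fit(
            _monoexp, t, m, p0=[m[0], max(k2_0, 1e-6)],
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
        )
        rms1 = float(np.sqrt(np.mean((m - _monoexp(t, *p1)) ** 2)))
    except RuntimeError:
        p1, rms1 = None, np.inf

    # two-term fit --------------------------------------------------------
    try:
        p2, _ = curve_fit(
            _biexp, t, m, p0=[amp0, w0, max(k1_0, 1e-6), max(k2_0, 0.0)],
            bounds=([0, 0, 0, 0], [np.inf, 1, np.inf, np.inf]), maxfev=20000,
        )
        last_params = p2
        rms2 = float(np.sqrt(np.mean((m - _biexp(t, *p2)) ** 2)))
    except RuntimeError:
        p2, rms2 = None, np.inf

    if p1 is None and p2 is None:
        raise FitError("neither single nor double exponential converged", last_params)

    use_double = p2 is not None and (p1 is None or rms2 <= 0.99 * rms1)
    if use_double:
        amp, w, ka, kb = p2
        a1, k1, a2, k2 = w, ka, 1 - w, kb
        if k2 > k1:  # enforce ordering convention k1 >= k2
            a1, k1, a2, k2 = a2, k2, a1, k1
        rms = rms2
    else:
        amp, k = p1
        a1, k1, a2, k2 = 1.0, float(k), 0.0, 0.0
        rms = rms1

    model = BleachModel(
        a1=float(a1), k1=float(k1), a2=float(a2), k2=float(k2),
        normalization=float(amp),
    )
    model.rms_residual = rms  # diagnostic, ADU
    return model


def apply_bleach_correction(stack: MovieStack, model: BleachModel) -> MovieStack:
    """Divide each frame by the normalized decay at its acquisition time.

    Frame 0 is unchanged (decay(0) = 1).  Being a per-frame scalar
    division, the correction preserves all within-frame intensity ratios.
    """
    d = model.decay(stack.times)
    if np.any(d <= 0):
        raise CorrectionError("decay is non-positive within the movie time span")
    corrected = stack.data / d[:, None, None, None]
    return stack.with_data(
        corrected,
        bleach_model={"a1": model.a1, "k1": model.k1, "a2": model.a2, "k2": model.k2},
    )


def bleach_correct(
    stack: MovieStack,
    target_fraction: float = 0.95,
    frames_used: int = 10,
    min_votes: int = 8,
):
    """Full automatic chain: histogram → mixture → threshold → mask → fit → apply.

    Returns
    -------
    corrected : MovieStack
    report : dict
        Mixture parameters, threshold, mask size, bleach parameters and
        residual RMS, plus the median intracellular trace.
    """
    frame0 = stack.sum_projection()[0]
    hist = BrightnessHistogram.from_image(frame0)
    mixture = fit_pixel_mixture(hist)
    threshold = intracellular_threshold(mixture, hist, target_fraction)
    mask = build_intracellular_mask(stack, threshold, frames_used, min_votes)
    model = fit_bleach_model(stack, mask)
    corrected = apply_bleach_correction(stack, model)
    report = {
        "mixture": {"background": mixture.background, "intracellular": mixture.intracellular},
        "threshold": threshold,
        "mask_pixels": mask.n_pixels,
        "bleach": {"a1": model.a1, "k1": model.k1, "a2": model.a2, "k2": model.k2,
                   "normalization": model.normalization},
        "rms_residual": getattr(model, "rms_residual", None),
        "median_trace": median_intracellular_trace(stack, mask).tolist(),
    }
    return corrected, report
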