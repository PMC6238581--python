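"""Exception hierarchy for the patch-quantification pipeline."""


class PatchQuantError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(PatchQuantError, ValueError):
    """A scene/cell/patch specification violates its invariants."""


class GenerationError(PatchQuantError, ValueError):
    """Synthetic rendering cannot proceed (e.g. overlapping cells)."""


class DimensionError(PatchQuantError, ValueError):
    """Image shapes are inconsistent."""


class FlaggedPixelError(PatchQuantError, ValueError):
    """Flat-field contains unusable (zero/negative) pixels.

    Attributes
    ----------
    pixels : ndarray of (row, col)
        Offending pixel coordinates.
    """

    def __init__(self, message, pixels):
        super().__init__(message)
        self.pixels = pixels


class FitError(PatchQuantError, RuntimeError):
    """A least-squares fit failed to converge.

    Carries the last parameter vector (possibly None) for diagnosis.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DegenerateMixtureError(FitError):
    """Brightness histogram shows a single population: no threshold exists."""


class ThresholdError(PatchQuantError, RuntimeError):
    """No histogram bin reaches the requested intracellular purity."""


class MaskingError(PatchQuantError, RuntimeError):
    """Intracellular mask came out empty."""


class EmptyCropError(PatchQuantError, RuntimeError):
    """No pixel of the illumination model reaches the crop threshold."""


class CorrectionError(PatchQuantError, RuntimeError):
    """Bleach-correction divisor is non-positive within the movie."""


class SegmentationError(PatchQuantError, RuntimeError):
    """Cell segmentation retained no regions."""


class ConfigurationError(PatchQuantError, ValueError):
    """A required input (e.g. the nonfluorescent control strain) is missing."""


class InsufficientDataError(PatchQuantError, ValueError):
    """Too few strains/tracks/points for the requested fit."""


class CalibrationError(PatchQuantError, ValueError):
    """Calibration curve unusable (non-positive slope)."""


class DegenerateCurveError(PatchQuantError, ValueError):
    """Aligned curve has no usable signal (no point above the phase floor)."""


class InsufficientSpanError(PatchQuantError, ValueError):
    """Curve segment is shorter than the sliding fit window."""


class AlignmentWarning(UserWarning):
    """Track realignment hit max_iter before the offset tolerance."""
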