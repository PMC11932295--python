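"""Exception hierarchy for the cadmilume pipeline.

Every failure mode that a caller might want to catch separately gets its
own class; all inherit from :class:`CadmilumeError` so a CLI can catch the
base class and degrade gracefully.
"""


class CadmilumeError(Exception):
    """Base class for all cadmilume errors."""


class InputError(CadmilumeError):
    """Malformed or out-of-contract input (wrong shape, bad factor, ...)."""


class DegenerateHistogramError(CadmilumeError):
    """Otsu thresholding requested on a constant-intensity image."""


class LayoutMismatchError(CadmilumeError):
    """Number of detections does not match the number of occupied layout cells."""


class GridInferenceError(CadmilumeError):
    """Row splitting produced row sizes inconsistent with the layout."""


class BackgroundUnavailableError(CadmilumeError):
    """Background annulus is empty or entirely outside the image."""


class SaturationError(CadmilumeError):
    """Too many saturated pixels in a well core; the color is untrustworthy.

    The remedy is to retake the photograph at a lower exposure.
    """


class EmptyROIError(CadmilumeError):
    """No usable pixels remain in the region of interest."""


class InvalidColorError(CadmilumeError):
    """Color measurement sums to zero; chromaticity is undefined."""


class RatioUndefinedError(CadmilumeError):
    """Red channel is zero so the green/red ratio cannot be formed."""

    def __init__(self, message: str, coords=None):
        super().__init__(message)
        self.coords = coords


class InsufficientCalibrationError(CadmilumeError):
    """Fewer than three calibration points, or no concentration spread."""


class NonMonotoneCalibrationError(CadmilumeError):
    """Fitted slope is not negative: the assay failed or wells are mislabeled."""


class ConfigError(CadmilumeError):
    """Invalid plate-layout or synthetic-plate configuration."""


class SpecError(CadmilumeError):
    """Synthetic plate specification violates its own invariants."""
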