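"""Exception hierarchy for the mIOP pipeline.

Every stage raises a subclass of :class:`MiopError` so callers can catch
pipeline failures without masking programming errors.
"""


class MiopError(Exception):
    """Base class for all mIOP pipeline errors."""


class FormatError(MiopError):
    """Input file does not match the expected tabular layout."""


class SequenceError(MiopError):
    """Frame indices are missing, duplicated, or out of order."""


class InsufficientData(MiopError):
    """Too few samples for the requested operation."""


class DegenerateGeometry(MiopError):
    """Geometry fit is undefined (e.g. collinear points for a circle)."""


class GeometryError(MiopError):
    """Frames share no usable lateral support."""


class NoContourFound(MiopError):
    """Segmentation found no plausible corneal band in the image."""


class DomainError(MiopError):
    """Argument outside the mathematical domain of the operation."""


class RangeError(MiopError):
    """Invalid frame range (i >= j or outside 1..n_frames)."""


class DegenerateFeature(MiopError):
    """A feature denominator is numerically zero."""


class NoApplanation(MiopError):
    """No concave episode (curvature sign change) in the sequence."""


class ShapeError(MiopError):
    """Paired vectors have mismatched lengths or are too short."""


class DegenerateDesign(MiopError):
    """Regression design has zero variance in the covariate."""


class ConfigError(MiopError):
    """Invalid configuration value or missing required table column."""


class IopRangeWarning(UserWarning):
    """Estimated IOP falls outside the calibrated 8-30 mmHg range."""
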