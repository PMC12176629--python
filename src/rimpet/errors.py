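"""Exception hierarchy shared across the pipeline."""


class RimpetError(Exception):
    """Base class for all rimpet errors."""


class GridCompatibilityError(RimpetError):
    """Two volumes do not share the same shape/spacing grid."""


class ShapeError(RimpetError):
    """An array payload has the wrong dimensionality."""


class FitError(RimpetError):
    """A regression could not be performed (too few usable points)."""


class NumericDomainError(RimpetError):
    """Input values fall outside the numeric domain of an operation."""


class CalibrationError(RimpetError):
    """Threshold calibration received insufficient data."""


class UndefinedFractionError(RimpetError):
    """An active-voxel fraction was requested over an empty region."""


class LesionLookupError(RimpetError, KeyError):
    """A lesion id is absent from a label map."""


class GeometryError(RimpetError):
    """Contours violate a geometric precondition (containment, simplicity)."""


class ContourError(RimpetError):
    """A contour is degenerate (too few points, zero length)."""


class SamplingError(RimpetError):
    """A region is too small to place the requested sampling fields."""


class LabelError(RimpetError):
    """A patient timeline cannot support the requested label."""


class StatisticError(RimpetError):
    """A statistical test received degenerate input."""


class ConfigError(RimpetError):
    """Pipeline configuration violates an invariant."""
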