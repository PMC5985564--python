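"""Exception hierarchy for the droplet-mapping pipeline."""


class OleomapError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(OleomapError, ValueError):
    """Raised for empty or malformed input images/arrays."""


class DegenerateHistogramError(OleomapError, ValueError):
    """Histogram has all its mass in a single bin; no threshold exists."""


class EmptyMaskError(OleomapError, ValueError):
    """A binary mask that must contain foreground is empty."""


class AnnotationError(OleomapError, ValueError):
    """Center annotation missing, malformed, or out of image bounds."""


class GeometryError(OleomapError, ValueError):
    """Radial geometry is ill-posed (center outside contour, zero vector, ...)."""


class DomainError(OleomapError, ValueError):
    """A value lies outside its mathematical domain (e.g. pp outside [0, 100])."""


class ConsistencyError(OleomapError, ValueError):
    """Droplet lies far outside the edge contour; wrong center/edge pairing."""


class SyntheticSpecError(OleomapError, ValueError):
    """A synthetic-slice specification violates its own constraints."""


class MetadataError(OleomapError, ValueError):
    """Slice metadata fails validation (unknown factor levels, missing columns)."""


class UsageError(OleomapError, ValueError):
    """The operation was called in a statistically or structurally invalid way."""
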