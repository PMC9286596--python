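"""Package-specific error types."""


class PeatfireError(Exception):
    """Base class for all package errors."""


class SizingError(PeatfireError):
    """A grid is too small for the requested synthetic features."""


class MappingError(PeatfireError):
    """A raw land-cover class has no entry in the regrouping table."""


class AlignmentError(PeatfireError):
    """Rasters that must share a grid do not."""


class SamplingError(PeatfireError):
    """Training-point sampling failed (e.g. an empty occurrence space)."""


class GeometryError(PeatfireError):
    """Degenerate geometry input (zero-area bounds, empty feature set)."""


class NormalizationError(PeatfireError):
    """Cross-year or reference normalization is undefined for the input."""


class ExtentError(PeatfireError):
    """A fine grid extends beyond the coarse raster it is interpolated from."""
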