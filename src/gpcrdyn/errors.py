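"""Exception hierarchy shared across the package."""


class GpcrDynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GpcrDynError):
    """A required configuration item (anchor, selection spec, ...) is missing or invalid."""


class DataError(GpcrDynError):
    """Input data violate a documented precondition (e.g. anchor on a gap)."""


class FormatError(GpcrDynError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(GpcrDynError):
    """Degenerate or undefined geometry (collinear dihedral, <3 atoms for superposition)."""


class EstimationError(GpcrDynError):
    """A statistical model cannot be estimated from the given data."""


class FitError(GpcrDynError):
    """A nonlinear curve fit failed to converge."""
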