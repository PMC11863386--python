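"""Exception hierarchy shared across the package."""


class PreorgError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(PreorgError, ValueError):
    """An argument violates a documented precondition."""


class DimensionError(PreorgError, ValueError):
    """Mismatched feature/coordinate dimensionality."""


class SchemeError(PreorgError, ValueError):
    """A charge-neutralization scheme cannot be applied to this residue."""


class GeometryError(PreorgError, ValueError):
    """Missing or invalid atomic coordinates."""


class DataError(PreorgError, ValueError):
    """Empty or malformed input data series."""


class IntegrationError(PreorgError, RuntimeError):
    """A trajectory left the guarded domain (divergence)."""


class CoverageError(PreorgError, ValueError):
    """A quadrature/histogram grid fails to cover all basins."""


class SamplerError(PreorgError, RuntimeError):
    """Non-finite collective-variable value during biased sampling."""


class BatchError(PreorgError, ValueError):
    """A training batch has too few samples in some class."""


class ConfigError(PreorgError, ValueError):
    """Inconsistent model/training configuration."""


class ExtractionError(PreorgError, ValueError):
    """A state window contains no interior extremum."""


class CorrespondenceError(PreorgError, ValueError):
    """Superposition anchors do not correspond atom-by-atom."""


class MappingError(PreorgError, ValueError):
    """A reference sequence position cannot be mapped to an alignment column."""
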