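"""Exception and warning types shared across the package."""


class AARSpatialError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AARSpatialError):
    """Invalid simulation or pipeline configuration."""


class FormatError(AARSpatialError):
    """Malformed input file (MTX/TSV/positions/GMT)."""


class ValidationError(AARSpatialError):
    """Input data violates a documented precondition."""


class AARSpatialWarning(UserWarning):
    """Base class for package warnings."""


class EmptyResultWarning(AARSpatialWarning):
    """An operation produced an empty result (e.g. QC removed every spot)."""


class DegenerateDataWarning(AARSpatialWarning):
    """Data were degenerate for a statistic (ties everywhere, zero variance, ...)."""
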