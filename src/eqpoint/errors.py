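"""Exception hierarchy shared across the package."""


class EqpointError(Exception):
    """Base class for all package errors."""


class DomainError(EqpointError, ValueError):
    """Input lies outside the domain on which a curve or map is defined."""


class InputError(EqpointError, ValueError):
    """Malformed or non-finite input."""


class ModelError(EqpointError, RuntimeError):
    """A model-level contract failed (no bracketed root, redraw cap hit, ...)."""


class ConfigError(EqpointError, ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(EqpointError, ValueError):
    """Missing or malformed data file (CLI exit code 3)."""


class UndefinedCorrelationError(EqpointError, ValueError):
    """Correlation requested on data with zero variance in a coordinate."""
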