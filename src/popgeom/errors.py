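"""Exception hierarchy shared across the package."""


class PopgeomError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PopgeomError):
    """Raised when data violates a container invariant (NaN, negative activity, ...)."""


class SchemaError(PopgeomError):
    """Raised when an on-disk file or a configuration is structurally wrong."""


class ConfigError(PopgeomError):
    """Raised for invalid generator or pipeline configuration values."""


class LookupKeyError(PopgeomError, KeyError):
    """Raised when a neuron / class / variant / sequence key does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class DimensionError(PopgeomError):
    """Raised when a requested dimensionality exceeds what the data supports."""


class DegenerateClassError(PopgeomError):
    """Raised when a class has too few analysis units for the requested scheme."""


class InsufficientClassesError(PopgeomError):
    """Raised when a metric needs at least two trajectory classes."""
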