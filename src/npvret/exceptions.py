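"""Exception hierarchy shared across the package."""


class NpvretError(Exception):
    """Base class for all package errors."""


class ValidationError(NpvretError, ValueError):
    """An input value violates its documented bounds or structure."""


class ConfigurationError(NpvretError, RuntimeError):
    """Required package data or configuration is missing or malformed."""


class DimensionError(NpvretError, ValueError):
    """Arrays that must share a grid or shape do not."""


class UndefinedValueError(NpvretError, ArithmeticError):
    """A requested quantity is mathematically undefined for the inputs."""


class NoOverlapError(NpvretError, ValueError):
    """A band mask leaves no wavelengths of the input spectrum."""


class PoolExhausted(NpvretError):
    """An active-learning candidate pool has no remaining samples."""
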