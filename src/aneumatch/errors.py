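"""Exception hierarchy shared across the package."""


class AneumatchError(Exception):
    """Base class for all package errors."""


class ConfigError(AneumatchError):
    """Invalid configuration value (probability outside [0,1], k < 1, ...)."""


class SchemaError(AneumatchError):
    """Case table violates the column schema (missing column, bad value, duplicate id)."""


class DomainError(AneumatchError):
    """A scalar input is outside the mathematical domain of an operation."""


class MatchingError(AneumatchError):
    """Feature encoding or neighbor search cannot proceed (missing value, empty pool)."""


class UnmatchableError(MatchingError):
    """An aneurysm of interest has no admissible reference case left."""
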