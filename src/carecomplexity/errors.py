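"""Exception hierarchy shared across the package."""

__all__ = [
    "CareComplexityError",
    "ValidationError",
    "MissingDataError",
    "RangeError",
    "ConfigError",
    "InfeasibleConfigError",
]


class CareComplexityError(Exception):
    """Base class for all package errors."""


class ValidationError(CareComplexityError):
    """An input value violates a type invariant or schema."""


class MissingDataError(ValidationError):
    """A required field or observation is absent in strict mode."""


class RangeError(CareComplexityError):
    """A score or total lies outside its defined range."""


class ConfigError(CareComplexityError):
    """A configuration document is malformed."""


class InfeasibleConfigError(ConfigError):
    """A simulation configuration cannot be satisfied (e.g. day totals)."""
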