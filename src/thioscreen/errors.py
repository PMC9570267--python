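"""Exception hierarchy used across the package.

All errors derive from :class:`ThioscreenError` so callers can catch one
base class; more specific subclasses carry the contract of each failure
mode (schema vs parse vs validation vs domain).
"""


class ThioscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(ThioscreenError):
    """A table header or a named column set does not match the expected schema."""


class ParseError(ThioscreenError):
    """A cell could not be parsed as the required type (carries row/column)."""


class ValidationError(ThioscreenError):
    """A parsed value violates a record invariant."""


class DomainError(ThioscreenError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class DimensionError(ThioscreenError, ValueError):
    """Paired inputs have incompatible lengths or shapes."""


class FixtureLookupError(ThioscreenError, KeyError):
    """An unknown bundled-fixture name was requested."""


class ConfigurationError(ThioscreenError):
    """A policy or configuration object is invalid (e.g. collinear triangle)."""
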