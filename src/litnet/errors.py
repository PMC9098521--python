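"""Exception hierarchy shared across the package.

All data-level problems derive from :class:`LitnetError` so the CLI can map
them onto exit code 1; argument problems use :class:`UsageError` (exit 2).
"""


class LitnetError(Exception):
    """Base class for all package errors."""


class FormatError(LitnetError):
    """An input file violates its declared dialect (bad line, duplicate key)."""


class ValidationError(LitnetError):
    """Data is syntactically fine but violates a semantic contract."""


class StructuralError(LitnetError):
    """A hierarchy is malformed (cycles, missing root)."""


class UnknownIdError(LitnetError, KeyError):
    """An identifier was looked up that the loaded resource does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return Exception.__str__(self)


class QueryParseError(FormatError):
    """Boolean query text could not be parsed; carries a character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UsageError(LitnetError):
    """Caller combined arguments in an unsupported way."""
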