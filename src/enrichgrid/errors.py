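"""Exception hierarchy shared across the package."""


class EnrichGridError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EnrichGridError):
    """Malformed annotation input.

    Carries the 1-based line number of the first offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MissingRootError(EnrichGridError):
    """The requested category root is absent from the parsed graph."""


class FormatError(ParseError):
    """A tabular record is structurally invalid (missing column, bad value)."""


class CycleError(EnrichGridError):
    """Retained relations form a directed cycle; input is corrupt."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cycle detected: " + " -> ".join(map(str, self.cycle)))


class DomainError(EnrichGridError, ValueError):
    """An argument violates the operation's mathematical preconditions."""


class UnsupportedModeError(EnrichGridError):
    """The requested value/display mode is incompatible with the data."""


class InputError(EnrichGridError):
    """User-supplied ids or structures are inconsistent (duplicates, unknowns)."""
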