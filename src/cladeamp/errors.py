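"""Exception hierarchy shared across the toolkit."""


class CladeampError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CladeampError):
    """Input violates a domain invariant (bad residue, empty group, ...)."""


class ParseError(CladeampError):
    """A file could not be parsed; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CapacityError(CladeampError):
    """An expansion or enumeration would exceed a configured ceiling."""


class ConfigurationError(CladeampError):
    """Unknown method identifier or invalid parameter combination."""


class BoundsError(CladeampError):
    """A coordinate falls outside the sequence it refers to."""


class MappingError(CladeampError):
    """An alignment window cannot be mapped onto the reference row."""


class InsufficientDataError(CladeampError):
    """Too few observations to fit or estimate."""
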