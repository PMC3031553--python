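"""Exception hierarchy shared across the package."""


class SeaSightError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SeaSightError):
    """A column map, dialect or pipeline configuration is incomplete or invalid."""


class ParseError(SeaSightError):
    """A source file could not be parsed; carries a line number when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ParameterError(SeaSightError):
    """An operation parameter is out of its admissible range."""


class StateError(SeaSightError):
    """A transformation was applied to data in an incompatible state."""


class DomainError(SeaSightError):
    """A numeric operation was called outside its mathematical domain."""


class FitError(SeaSightError):
    """A model fit failed on degenerate input."""
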