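"""Exception hierarchy for the stress-profile curvature pipeline."""


class MemcurvError(Exception):
    """Base class for all package errors."""


class ParseError(MemcurvError, ValueError):
    """A stress-table row could not be parsed (carries the 1-based line number)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class FormatError(MemcurvError, ValueError):
    """Column layout does not match any supported dialect."""


class InsufficientDataError(MemcurvError, ValueError):
    """Fewer data rows / samples than the operation requires."""


class ConfigurationError(MemcurvError, ValueError):
    """Invalid dialect name or parameter combination."""


class DomainError(MemcurvError, ValueError):
    """Argument outside the mathematical domain of the operation."""


class StateError(MemcurvError, RuntimeError):
    """Profile not centered/oriented for the requested operation."""
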