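"""Exception hierarchy shared across the toolkit."""


class SwcnvError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SwcnvError):
    """A text input could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SwcnvError):
    """Input values violate a documented precondition."""


class DegenerateDispersionError(SwcnvError):
    """MAD of the signal is zero, so a median +/- k*MAD threshold collapses.

    Raised instead of silently calling everything; callers may supply an
    explicit absolute threshold to proceed.
    """
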