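"""Exception hierarchy.

All errors raised by the package derive from :class:`CardioTraceError` so callers
can catch the package's failures with a single except clause; each subclass also
derives from the matching builtin so untouched code keeps working.
"""


class CardioTraceError(Exception):
    """Base class for all cardiotrace errors."""


class ParameterError(CardioTraceError, ValueError):
    """A configuration or parameter value violates its stated constraint."""


class InputError(CardioTraceError, ValueError):
    """Input data (a stream, trace, or span) is malformed or out of range."""


class FormatError(CardioTraceError, ValueError):
    """A record file could not be parsed.

    Attributes
    ----------
    line : int or None
        1-based line number of the offending line, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
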