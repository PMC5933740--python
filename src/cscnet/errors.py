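"""Exception hierarchy shared across the package."""


class CscnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CscnetError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(CscnetError, ValueError):
    """An input file does not conform to its documented dialect.

    Carries the offending path and, when known, the 1-based line number
    (or XML element identifier) so errors can be located in the source.
    """

    def __init__(self, message: str, *, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ConsistencyError(CscnetError, ValueError):
    """Inputs to an operation contradict each other."""


class UsageError(CscnetError, ValueError):
    """An operation was invoked in an unsupported way."""
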