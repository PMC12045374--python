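"""Exception types shared across the package."""


class PausekitError(Exception):
    """Base class for all pausekit errors."""


class ParseError(PausekitError):
    """A file could not be parsed under the declared dialect.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(PausekitError):
    """Input parsed but violates a contract (coordinates, ranges, duplicates)."""
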