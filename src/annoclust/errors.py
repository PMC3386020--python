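"""Exception types shared across the package."""


class AnnoclustError(Exception):
    """Base class for all package errors."""


class ParseError(AnnoclustError):
    """A malformed input file (carries the offending line number when known)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigurationError(AnnoclustError):
    """Inconsistent or incomplete run parameters."""
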