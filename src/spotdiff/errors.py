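"""Exception types shared across the package."""


class SpotdiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpotdiffError, ValueError):
    """A configuration object or parameter violates its invariants."""


class SpotTableFormatError(SpotdiffError, ValueError):
    """A spot-table or annotation file is malformed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateGelError(SpotdiffError, ValueError):
    """A gel table admits no meaningful computation (e.g. all-zero volumes)."""
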