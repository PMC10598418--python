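"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`TrossaError`
so callers can catch domain failures without swallowing programming errors.
"""


class TrossaError(Exception):
    """Base class for all errors raised by the trossa package."""


class SchemaError(TrossaError):
    """A required column is missing or a table does not match its dialect."""


class RowParseError(TrossaError):
    """A data row could not be parsed; carries the zero-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DomainError(TrossaError, ValueError):
    """An argument is outside its scientific domain (e.g. non-positive effort)."""


class MatchingError(TrossaError):
    """No control trossa is available to pair with a deterrent trossa."""


class ConfigurationError(TrossaError):
    """A species group, generator setting or pipeline option is invalid."""


class StageError(TrossaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
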