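"""Exception hierarchy shared across the pipeline stages."""


class SpiroQCError(Exception):
    """Base class for all spiroqc errors."""


class InvalidParameterError(SpiroQCError, ValueError):
    """A maneuver or configuration parameter violates its constraints."""


class LayoutError(SpiroQCError, ValueError):
    """A report layout places plots outside their allowed area."""


class ReportFormatError(SpiroQCError, ValueError):
    """A report file cannot be interpreted (wrong type, zero pages, ...)."""


class MissingFieldError(SpiroQCError, KeyError):
    """A required demographic field is absent from the report text."""

    def __init__(self, field: str):
        super().__init__(field)
        self.field = field

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return f"missing demographic field: {self.field}"


class NoCurvesFoundError(SpiroQCError, ValueError):
    """Fewer than two curve regions survive filtering in the bottom half."""


class StageError(SpiroQCError, RuntimeError):
    """Wraps a failure inside the construct pipeline with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
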