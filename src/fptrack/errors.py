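"""Exception types shared across the pipeline."""


class FptrackError(Exception):
    """Base class for all package errors."""


class SchemaError(FptrackError):
    """An input table is missing a required column."""


class RowParseError(FptrackError):
    """One or more rows of an input table could not be parsed.

    Carries the 1-based line numbers of the offending rows.
    """

    def __init__(self, message: str, lines: list[int]):
        super().__init__(f"{message} (lines: {lines})")
        self.lines = lines


class ScaleUndetectableError(FptrackError):
    """No radius attained enough defined first-passage times to score."""


class OutOfWindowError(FptrackError):
    """A point or raster falls outside the configured analysis window."""


class PipelineStageError(FptrackError):
    """A pipeline stage failed; names the stage and offending unit."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}': {detail}")
        self.stage = stage
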