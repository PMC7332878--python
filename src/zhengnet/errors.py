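"""Typed errors raised across the pipeline.

Every reader and pipeline stage fails with one of these instead of silently
truncating or returning partial results.
"""


class ZhengnetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ZhengnetError, ValueError):
    """A generator or operation parameter is outside its legal range."""


class ValidationError(ZhengnetError, ValueError):
    """Input data violates a structural invariant (duplicates, collisions...)."""


class ParseError(ZhengnetError, ValueError):
    """A file does not conform to its declared dialect.

    Carries ``location`` (byte offset or line number) when known.
    """

    def __init__(self, message: str, location: int | None = None):
        self.location = location
        if location is not None:
            message = f"{message} (at {location})"
        super().__init__(message)


class TermLookupError(ZhengnetError, KeyError):
    """A symptom or term queried at use-time has no mapping."""


class FeatureMapMismatchError(ZhengnetError, ValueError):
    """A model was applied with a featurizer it was not trained with."""


class PipelineStageError(ZhengnetError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
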