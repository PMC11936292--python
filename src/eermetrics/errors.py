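"""Exception hierarchy shared across the pipeline."""


class EERMetricsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EERMetricsError, ValueError):
    """Scene or configuration parameters violate their invariants."""


class ValidationError(EERMetricsError, ValueError):
    """Input data (table, mask, file) failed schema validation."""


class DetectionError(EERMetricsError, RuntimeError):
    """Circle detection could not produce an admissible pupil/iris pair.

    ``missing`` names which circle could not be found ("pupil", "iris" or
    "pair").
    """

    def __init__(self, message: str, missing: str = "pair"):
        super().__init__(message)
        self.missing = missing


class DegenerateEyeError(EERMetricsError, RuntimeError):
    """The eye region is degenerate (e.g. closed aperture, empty whole area)."""


class PipelineStageError(EERMetricsError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
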