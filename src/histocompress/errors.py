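"""Exception types shared across the package."""


class HistocompressError(Exception):
    """Base class for all package errors."""


class ParameterError(HistocompressError, ValueError):
    """Invalid user-supplied parameter."""


class OvercrowdingError(ParameterError):
    """Requested cell density cannot be placed without pathological overlap."""


class DimensionError(HistocompressError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class SceneFormatError(HistocompressError, IOError):
    """A scene directory is missing or has a corrupt component file."""


class CodecError(HistocompressError, RuntimeError):
    """The underlying image codec failed."""


class ConvergenceError(CodecError):
    """Rate search could not reach the requested PSNR target.

    Carries the closest encoding achieved so callers can fall back to a
    best-effort result.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        #: ``(bytes, CompressionRecord)`` of the closest attempt, or None.
        self.best = best


class EmptyClassError(HistocompressError, ValueError):
    """Positive patches were requested from a scene with no positive pixels."""


class TrainingError(HistocompressError, ValueError):
    """Training set does not permit fitting (e.g. single class)."""


class UndefinedMetricError(HistocompressError, ValueError):
    """Metric is mathematically undefined for the given ground truth."""


class DegenerateGeometryError(HistocompressError, ValueError):
    """Too few or degenerate points for any spatial-graph construction."""

    def __init__(self, message, skipped=()):
        super().__init__(message)
        #: families that could not be computed
        self.skipped = tuple(skipped)


class PipelineStageError(HistocompressError, RuntimeError):
    """A sweep stage failed; the message names the stage."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
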