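"""Exception hierarchy shared across the pipeline stages."""


class TrackRSFError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TrackRSFError, ValueError):
    """A configuration value violates its invariants."""


class EmptyInputError(TrackRSFError, ValueError):
    """An operation received an empty track or table."""


class OrderingError(TrackRSFError, ValueError):
    """Timestamps are not strictly increasing."""


class OutOfExtentError(TrackRSFError, ValueError):
    """A location falls outside the grid extent."""


class MissingLayerError(TrackRSFError, KeyError):
    """No raster layer exists for the requested date."""


class InsufficientDataError(TrackRSFError, ValueError):
    """Too few observations to fit a model."""


class DegenerateDataError(TrackRSFError, ValueError):
    """Input data carry no usable signal (e.g. all speeds zero)."""


class StepGenerationError(TrackRSFError, RuntimeError):
    """Candidate-step generation failed (e.g. all candidates on land)."""


class SimulationStuckError(TrackRSFError, RuntimeError):
    """A simulated track could not advance off land within the retry budget."""


class SeparationError(TrackRSFError, RuntimeError):
    """Perfect separation detected in a logistic fit."""


class InsufficientReplicatesError(TrackRSFError, ValueError):
    """Fewer than two converged replicate fits are available."""


class IncompleteProfileError(TrackRSFError, ValueError):
    """A selection-curve profile is missing a required covariate."""


class CoverageError(TrackRSFError, ValueError):
    """Environmental coverage gaps exceed the allowed fraction."""


class PipelineStageError(TrackRSFError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
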