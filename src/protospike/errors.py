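"""Exception hierarchy for protospike."""


class ProtospikeError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(ProtospikeError):
    """A trace file could not be parsed (non-numeric cells, wrong columns)."""


class NonMonotoneTimeError(TraceFormatError):
    """The time column of a trace file is not strictly increasing."""


class NonUniformSamplingError(TraceFormatError):
    """Successive time deltas deviate from a uniform sampling interval."""


class UnitMismatchError(ProtospikeError):
    """An operation received a trace in the wrong unit (mV vs uA)."""


class InfeasibleMomentsError(ProtospikeError):
    """Requested distribution moments cannot be realised by the chosen family."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


class InsufficientSpikesError(ProtospikeError):
    """Fewer spikes than required for the requested statistic."""


class NoPeriodicityError(ProtospikeError):
    """No dominant spectral peak found; the signal is spectrally flat."""


class PipelineStageError(ProtospikeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
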