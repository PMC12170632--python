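"""Exception hierarchy for the synergy-analysis pipeline."""


class MuscleSynError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MuscleSynError, ValueError):
    """A configuration value violates its documented range."""


class InvalidRateError(MuscleSynError, ValueError):
    """Sampling rate incompatible with the requested filter band."""


class InvalidWindowError(MuscleSynError, ValueError):
    """Onset/offset window is empty or reversed."""


class InvalidReferenceError(MuscleSynError, ValueError):
    """Non-positive normalization reference (e.g. MVIC <= 0)."""

class DomainError(MuscleSynError, ValueError):
    """Input outside the mathematical domain of an operation."""


class InvalidOrderError(MuscleSynError, ValueError):
    """Requested factorization order k is out of range."""


class UndefinedVAFError(MuscleSynError, ValueError):
    """VAF requested for an all-zero reference matrix."""


class UndefinedSimilarityError(MuscleSynError, ValueError):
    """Similarity requested for a zero vector."""


class LabelMismatchError(MuscleSynError, ValueError):
    """Two objects carry incompatible muscle label sets."""


class InfeasibleFrameError(MuscleSynError, RuntimeError):
    """A static-optimization frame has no feasible activation vector."""

    def __init__(self, message, joint=None, shortfall=None, frame=None):
        super().__init__(message)
        self.joint = joint
        self.shortfall = shortfall
        self.frame = frame


class PipelineStageError(MuscleSynError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending file."""

    def __init__(self, stage, message, path=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.path = path
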