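"""Exception hierarchy for notoroot."""


class NotorootError(Exception):
    """Base class for all package-specific errors."""


class BelowStandardError(NotorootError):
    """Specimen weight falls under the grade-IV floor and cannot be graded."""


class SpecError(NotorootError, ValueError):
    """A generator or pipeline specification violates its invariants."""


class InputError(NotorootError, ValueError):
    """An operation received structurally invalid input."""


class ParameterError(NotorootError, ValueError):
    """An operation received an out-of-range parameter."""


class DegenerateHistogramError(NotorootError):
    """Thresholding a constant image: the histogram has a single level."""


class DegenerateTextureError(NotorootError):
    """No valid pixel pair exists for the requested co-occurrence offset."""


class SegmentationError(NotorootError):
    """Preprocessing produced an empty foreground."""


class DivergenceError(NotorootError):
    """Iterative training produced non-finite loss; lower the learning rate."""


class StageError(NotorootError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
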