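"""Exception hierarchy for the vapor-qSIP pipeline.

Every error raised on purpose by this package derives from :class:`VaporQsipError`
so callers can catch pipeline failures without masking programming errors.
"""


class VaporQsipError(Exception):
    """Base class for all vapor-qSIP errors."""


class DegenerateSpecError(VaporQsipError, ValueError):
    """Dosing spec has no solution (added enrichment equals the target)."""


class InfeasibleTargetError(VaporQsipError, ValueError):
    """Target enrichment cannot be reached with the given added water."""


class EmptyMixtureError(VaporQsipError, ValueError):
    """Mixing two zero volumes has no defined enrichment."""


class InsufficientDataError(VaporQsipError, ValueError):
    """Too few observations for the requested fit or test."""


class CurveFitError(VaporQsipError, RuntimeError):
    """Non-convergent enrichment-curve fit; carries the last residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class ScenarioError(VaporQsipError, KeyError):
    """Unknown synthetic-community scenario name."""


class UncorrectableTubeError(VaporQsipError, ValueError):
    """A flagged tube has no unflagged reference tubes in its group."""


class EmptySampleError(VaporQsipError, ValueError):
    """A sample has zero total gene copies (or zero reads) after filtering."""


class UndefinedAssimilationError(VaporQsipError, ValueError):
    """Proportional assimilation is undefined (all growth rates zero)."""


class InvalidLabelError(VaporQsipError, ValueError):
    """Soil-water enrichment is non-positive; growth rates undefined."""


class DesignError(VaporQsipError, ValueError):
    """Statistical design is degenerate (single level, empty cell, ...)."""


class SchemaError(VaporQsipError, ValueError):
    """Input tables fail schema or cross-reference validation."""


class PipelineError(VaporQsipError, RuntimeError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
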