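"""Exception hierarchy for the EA pipeline.

Every stage raises a subclass of :class:`EAPipelineError`, so callers can
catch pipeline-specific failures without masking programming errors.
"""


class EAPipelineError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(EAPipelineError, ValueError):
    """A parameter violates a documented precondition."""


class DegenerateSeriesError(EAPipelineError):
    """A series is constant (or became constant), so the statistic is undefined."""


class TooShortClipError(EAPipelineError):
    """A clip has too few bins to survive edge truncation."""


class PairingError(EAPipelineError):
    """Perceiver and target series do not belong to the same clip."""


class DegeneratePairError(EAPipelineError):
    """An aligned pair has fewer than the minimum number of common bins."""


class InfeasibleOrderError(EAPipelineError):
    """No clip order satisfies the presentation constraints."""


class UndefinedStatisticError(EAPipelineError):
    """A summary statistic is undefined for the given inputs (e.g. zero variance)."""


class ParseError(EAPipelineError):
    """A CSV file does not conform to the documented dialect."""


class ConvergenceError(EAPipelineError):
    """The mixed-model optimizer failed to converge."""
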