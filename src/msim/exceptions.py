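"""Exception hierarchy for the msim package."""


class MsimError(Exception):
    """Base class for all msim-specific errors."""


class ParameterError(MsimError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DimensionError(MsimError, ValueError):
    """Array shapes of interacting objects do not agree."""


class DomainError(MsimError, ValueError):
    """Input values violate a domain constraint (e.g. negative intensities)."""


class DegenerateInputError(MsimError, ValueError):
    """An input is degenerate for the requested operation (e.g. empty pattern)."""


class ConditioningError(MsimError, ValueError):
    """A linear system is singular or too ill-conditioned to solve.

    Carries the condition number of the offending matrix.
    """

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


class EstimationError(MsimError, RuntimeError):
    """Illumination-parameter estimation failed.

    ``diagnostic`` holds the power spectrum that was searched, for inspection.
    """

    def __init__(self, message: str, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic


class LayoutError(MsimError, ValueError):
    """Synthetic-target elements overlap or fall outside the canvas."""


class RangeError(MsimError, ValueError):
    """A frequency shift exceeds the Nyquist limit of the target grid."""
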