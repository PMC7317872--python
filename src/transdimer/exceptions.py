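"""Exception hierarchy shared across the analysis modules."""


class TransdimerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TransdimerError, ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateInputError(TransdimerError, ValueError):
    """Input data carry no usable information (e.g. constant values)."""


class FitFailureError(TransdimerError, RuntimeError):
    """A least-squares fit failed to converge or produced an unphysical result.

    The ``diagnostics`` attribute, when set, holds solver output useful for
    post-mortem inspection.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class AggregationError(FitFailureError):
    """Low-q upturn in a scattering profile: Guinier analysis impossible."""


class OutOfDomainError(TransdimerError, ValueError):
    """A value lies outside the mathematical domain of a transform."""
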