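"""Exception hierarchy shared across the pipeline stages."""


class PreycapError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PreycapError, ValueError):
    """A parameter value is outside its valid domain."""


class DegenerateInputError(PreycapError, ValueError):
    """Input data is degenerate (constant trace, all-invalid frames, ...)."""


class ShapeError(PreycapError, ValueError):
    """Array shapes are inconsistent."""


class CapacityError(PreycapError, ValueError):
    """Requested events cannot fit in the recording length."""


class InstabilityError(PreycapError, ValueError):
    """A vector-autoregressive specification is not stationary."""


class MissingRegionError(PreycapError, KeyError):
    """A labelled region is empty or absent from the mask."""


class InvalidDelayError(PreycapError, ValueError):
    """A delay-embedding shift exceeds the recording length."""


class InsufficientSamplesError(PreycapError, ValueError):
    """Too few samples for the requested statistic."""


class InsufficientDataError(PreycapError, ValueError):
    """Too few data points (e.g. significant pixels) for a summary."""


class UndefinedProbabilityError(PreycapError, ZeroDivisionError):
    """A probability is requested from an empty event train."""


class NoValidEventError(PreycapError, ValueError):
    """All events fall too close to the recording edges."""


class InvalidEpochError(PreycapError, ValueError):
    """A condition epoch is empty or malformed."""


class EpochTooShortError(PreycapError, ValueError):
    """An epoch is too short for the requested autoregressive order."""


class UnstableEstimateError(PreycapError, ArithmeticError):
    """A bootstrap ratio statistic is unstable (denominator near zero)."""


class ConvergenceError(PreycapError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class ConfigError(PreycapError, ValueError):
    """A run configuration is invalid or internally inconsistent."""
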