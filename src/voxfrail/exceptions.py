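"""Exception hierarchy used across the pipeline."""


class VoxfrailError(Exception):
    """Base class for all package errors."""


class ValidationError(VoxfrailError, ValueError):
    """A parameter object or input table violates its invariants."""


class SizeError(ValidationError):
    """A requested synthesis would exceed the configured sample budget."""


class ConfigurationError(VoxfrailError, ValueError):
    """Inconsistent pipeline or cohort configuration."""


class NoSpeechError(VoxfrailError):
    """Endpoint detection found no frame above the speech threshold."""


class InsufficientDataError(VoxfrailError):
    """Too little signal (or too few valid frames/repeats) for an estimate."""


class UndefinedRatioError(VoxfrailError, ZeroDivisionError):
    """A spectral ratio is requested on a zero-energy signal."""


class ZeroVarianceError(VoxfrailError, ValueError):
    """The exposure is constant, so no association model is identifiable."""


class SeparationError(VoxfrailError):
    """Perfect or quasi-perfect separation: the logistic MLE diverges."""


class NonConvergenceError(VoxfrailError):
    """The optimizer did not converge within the iteration budget."""
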