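"""Exception types shared across the pipeline."""


class EpwvError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EpwvError, ValueError):
    """A value violates an operation's preconditions."""


class ConfigError(EpwvError, ValueError):
    """A preset or study configuration is malformed."""


class FormatError(EpwvError, ValueError):
    """A serialized file violates its schema."""


class InsufficientSignalError(EpwvError, RuntimeError):
    """Too little usable signal (or too few valid beats) to proceed."""


class ImplausibleTimingError(EpwvError, RuntimeError):
    """Detected timings are physiologically impossible (e.g. cPAT <= 0)."""


class SingularDesignError(EpwvError, RuntimeError):
    """Regression design matrix is rank deficient."""


class DegenerateInputError(EpwvError, ValueError):
    """Input is degenerate for the requested statistic (e.g. constant vector)."""


class UndefinedCorrelationError(EpwvError, RuntimeError):
    """Correlation is undefined because residuals are (near-)constant."""


class UnsupportedModelError(EpwvError, ValueError):
    """Closed-form oracle requested for a preset outside the calibrated model."""
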