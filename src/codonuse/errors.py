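"""Exception hierarchy shared across the package."""


class CodonUsageError(Exception):
    """Base class for all package errors."""


class FrameError(CodonUsageError):
    """Sequence length is not a multiple of three."""


class AlphabetError(CodonUsageError):
    """Sequence contains a base outside A/C/G/T."""


class EmptyInputError(CodonUsageError):
    """An operation received no usable input."""


class UndefinedMetricError(CodonUsageError):
    """A metric is undefined for the given counts (e.g. zero total)."""


class InsufficientDataError(CodonUsageError):
    """Not enough genes/observations to run the requested procedure."""


class FormatError(CodonUsageError):
    """A file did not parse under the expected format."""


class DomainError(CodonUsageError):
    """A numeric argument is outside its mathematical domain."""


class ModelError(CodonUsageError):
    """A synthetic usage model is internally inconsistent."""


class ConfigError(CodonUsageError):
    """A pipeline configuration value is out of range or inconsistent."""


class DegenerateFitError(CodonUsageError):
    """A regression/decomposition input has no usable variation."""
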