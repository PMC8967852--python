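"""Exception hierarchy for the pipeline."""


class IctalfeatError(Exception):
    """Base class for all package errors."""


class ConfigError(IctalfeatError, ValueError):
    """Invalid generator or pipeline configuration."""


class ParameterError(IctalfeatError, ValueError):
    """Invalid operation parameter (e.g. filter frequency above Nyquist)."""


class DataError(IctalfeatError, ValueError):
    """Input data violates a precondition (non-finite samples, too short)."""


class DegenerateEpochError(DataError):
    """An epoch carries no usable signal (all-zero, zero total power)."""


class ShapeError(IctalfeatError, ValueError):
    """Model input arity does not match the model specification."""


class LeakageError(IctalfeatError, RuntimeError):
    """A subject's epochs would be encoded by a model trained on that subject."""


class TrainingError(IctalfeatError, RuntimeError):
    """Optimization diverged (non-finite loss)."""
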