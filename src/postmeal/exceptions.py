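"""Exception hierarchy shared across the package."""


class PostmealError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PostmealError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive width)."""


class ConfigError(PostmealError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class InsufficientDataError(PostmealError, ValueError):
    """Too few observations to perform the requested computation."""


class MissingTimepointError(PostmealError, KeyError):
    """A required sampling time is absent from a curve or marker series."""


class SchemaError(PostmealError, ValueError):
    """An input table does not conform to the documented column schema."""


class EstimationError(PostmealError, RuntimeError):
    """An estimator failed (degenerate inputs, non-convergence, ...)."""
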