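"""Exception types raised across the pipeline."""


class SigwashError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SigwashError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class DegenerateBaselineError(InvalidInputError):
    """Baseline PWT is zero or negative, so normalization is undefined."""


class UnderdeterminedFitError(SigwashError, ValueError):
    """Fewer observations than the five-parameter model can support."""


class UndefinedDeviationError(SigwashError, ZeroDivisionError):
    """Percent deviation is undefined because the target has zero power (SSR = 0)."""


class InsufficientDataError(SigwashError, ValueError):
    """Too few paired observations for a statistical comparison."""


class SchemaError(SigwashError, ValueError):
    """Input table does not match the required long-format CSV schema."""
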