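"""Exception hierarchy shared across the pipeline stages."""


class DepscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(DepscreenError, ValueError):
    """Invalid generator or pipeline configuration."""


class ValidationError(DepscreenError, ValueError):
    """Invalid data handed to an operation (out-of-range item, shape mismatch...)."""


class InsufficientDataError(DepscreenError, ValueError):
    """Too few observations for the requested model."""


class CollinearityError(DepscreenError, ValueError):
    """Rank-deficient design matrix in the regression stage."""


class UndefinedStatisticError(DepscreenError, ValueError):
    """A statistic is undefined for the given input (zero variance etc.)."""
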