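"""Exception hierarchy for weedcomp."""


class WeedcompError(Exception):
    """Base class for all weedcomp errors."""


class DomainError(WeedcompError, ValueError):
    """Model evaluated outside its mathematical domain (pole, no maximum, ...)."""


class RangeError(WeedcompError, ValueError):
    """A requested window or value lies outside the available data span."""


class DesignError(WeedcompError, ValueError):
    """The observation design cannot support the requested fit."""


class ConvergenceError(WeedcompError, RuntimeError):
    """Nonlinear least squares failed to converge after multi-start."""


class ConsistencyError(WeedcompError, ValueError):
    """Fits being compared were not computed on the same observations."""


class SchemaError(WeedcompError, ValueError):
    """Tabular input violates the observation or temperature schema."""


class UndefinedStatisticError(WeedcompError, ValueError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""


class UnstableFitWarning(UserWarning):
    """A fitted parameter has a standard error much larger than the estimate."""
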