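"""Exception hierarchy shared across the package."""


class SepsisEvalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SepsisEvalError):
    """An invalid configuration value; the message names the offending field."""


class ContractViolationError(SepsisEvalError):
    """An input violated a documented precondition (e.g. unsorted times)."""


class UndefinedMetricError(SepsisEvalError):
    """A metric is undefined on the given sample (e.g. a single-class sample)."""


class BootstrapError(SepsisEvalError):
    """Bootstrap resampling failed too often to produce a reliable estimate."""


class UnreachableTargetError(SepsisEvalError):
    """A requested operating point (e.g. target sensitivity) cannot be reached."""
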