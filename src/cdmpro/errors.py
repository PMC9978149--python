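"""Exception hierarchy shared across the package."""


class CDMError(Exception):
    """Base class for all package errors."""


class ParameterError(CDMError):
    """Invalid or inconsistent model parameters (e.g. implied probability outside [0, 1])."""


class InputError(CDMError):
    """Malformed input data (non-binary responses, out-of-range Likert codes, ...)."""


class ConstructionError(CDMError):
    """A Q-matrix or constraint could not be constructed from the given specification."""


class RuleError(CDMError):
    """The outcome dichotomization rule is undefined (e.g. zero-variance change scores)."""


class NestingError(CDMError):
    """Likelihood-ratio comparison requested between non-nested fits."""


class UndefinedMetricError(CDMError):
    """A statistic is undefined for the given input (single-class outcome, flat item, ...)."""


class ConfigError(CDMError):
    """Invalid run configuration."""
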