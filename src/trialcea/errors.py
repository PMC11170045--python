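"""Exception hierarchy shared across the pipeline stages."""


class TrialCEAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrialCEAError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(TrialCEAError):
    """Invalid data value (negative price, missing field, ...)."""


class MissingDataError(TrialCEAError):
    """An operation that requires complete data met a missing value.

    Raised by endpoint conversion and cumulative costing when they hit
    unimputed cells: run the imputation stage first.
    """


class DegenerateDataError(TrialCEAError):
    """Data that makes an estimator undefined (constant endpoint, rank loss)."""
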