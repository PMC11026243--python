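"""Exception hierarchy shared across the pipeline stages."""


class CCWError(Exception):
    """Base class for all package errors."""


class ConfigError(CCWError, ValueError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(CCWError, KeyError):
    """A required column is missing from an input table."""


class InputError(CCWError, ValueError):
    """Invalid scalar input to an operation."""


class DataError(CCWError, ValueError):
    """Input data violate a structural invariant (e.g. non-absorbing treatment)."""


class FittingError(CCWError, RuntimeError):
    """A probability model could not be fitted."""


class PositivityError(CCWError, ValueError):
    """A predicted probability used in a weight denominator is 0 or 1."""


class PositivityWarning(UserWarning):
    """Fitted probabilities close enough to 0/1 to produce extreme weights."""
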