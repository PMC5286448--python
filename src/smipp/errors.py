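"""Exception hierarchy for the smipp package."""


class SmippError(Exception):
    """Base class for all package errors."""


class InvalidParametersError(SmippError, ValueError):
    """Raised when generator or model parameters violate their invariants."""


class InsufficientDataError(SmippError, ValueError):
    """Raised when an operation receives fewer usable points than it requires."""


class DegenerateDesignError(SmippError, ValueError):
    """Raised when a regression design matrix is rank deficient.

    The message names the offending predictor where it can be identified.
    """


class FormatError(SmippError, ValueError):
    """Raised when an input file does not conform to the expected layout."""


class ConfigError(SmippError, ValueError):
    """Raised when a pipeline configuration fails validation."""
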