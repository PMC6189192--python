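"""Exception hierarchy.

The CLI maps these onto distinct exit codes (usage=2, data=3, numerical=4).
"""


class PRTFError(Exception):
    """Base class for all package errors."""


class ConfigError(PRTFError):
    """Invalid configuration or parameter values."""


class DataError(PRTFError):
    """Input data violates a precondition (empty sets, negative times, ...)."""


class UsageError(PRTFError):
    """Objects combined inconsistently (mismatched nulls, sample universes, ...)."""


class FitError(PRTFError):
    """Numerical fitting failed (rank deficiency with no identifiable subset,
    non-convergence, collinear covariates)."""


class ParseError(DataError):
    """Malformed input file; carries the offending line number when known."""
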