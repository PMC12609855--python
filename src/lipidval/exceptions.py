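"""Exception hierarchy.

Exit-code mapping used by the CLI: input problems (ParameterError,
SchemaError) -> 1, estimation problems (EstimationError and subclasses) -> 2.
"""


class LipidvalError(Exception):
    """Base class for all package errors."""


class ParameterError(LipidvalError, ValueError):
    """An argument or configuration value is invalid; names the field."""


class SchemaError(LipidvalError, KeyError):
    """A required column/predictor is missing or mis-typed; names it."""


class EstimationError(LipidvalError, RuntimeError):
    """A model fit failed (non-convergence, perfect separation, ...)."""


class DegenerateInputError(EstimationError):
    """Input admits no estimate (single outcome class, constant predictor)."""
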