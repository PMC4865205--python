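"""Exception types shared across the package."""


class FDBError(Exception):
    """Base class for all fdbseg errors."""


class ParameterError(FDBError, ValueError):
    """An invalid parameter value (bad cutoffs, orders, thresholds, ...)."""


class EvaluationError(FDBError, ArithmeticError):
    """A numerical evaluation failed (e.g. an exact pole on the frequency grid)."""
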