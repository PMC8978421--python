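"""Exception hierarchy for rddframes."""


class RDDFramesError(Exception):
    """Base class for all package errors."""


class ConfigError(RDDFramesError):
    """Invalid configuration (shares not summing to one, impossible rates, ...)."""


class DataError(RDDFramesError):
    """Inconsistent respondent or frame data (e.g. e_LL = 0 with t_LL > 0)."""


class StructuralZeroError(RDDFramesError):
    """A raking target category has positive share but no sample support."""

    def __init__(self, variable: str, category: str):
        self.variable = variable
        self.category = category
        super().__init__(
            f"structural zero: margin '{variable}' category '{category}' has a "
            f"positive target share but zero weighted sample total"
        )


class ConvergenceError(RDDFramesError):
    """An iterative fit failed to converge."""
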