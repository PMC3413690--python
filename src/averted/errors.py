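"""Exception hierarchy shared across the package."""


class AvertedError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AvertedError):
    """An input file violates its documented column/row schema."""


class ValidationError(AvertedError):
    """An in-memory object violates a domain invariant."""


class InfeasibleError(AvertedError):
    """A requested transformation exceeds what the data can support
    (e.g. averting more deaths than an age interval contains)."""


class ConfigError(AvertedError):
    """A scenario or generator configuration is inconsistent."""


class DegenerateBaselineError(AvertedError):
    """Baseline coverage already removes every preventable death, so the
    residual-counterfactual normalisation 1 - E*AF*c0 vanishes."""


class UndefinedCoefficientError(AvertedError):
    """The Gini coefficient is undefined (mean age at death is zero)."""
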