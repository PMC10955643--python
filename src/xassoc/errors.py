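"""Exception hierarchy shared by all pipeline stages."""


class XassocError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XassocError, ValueError):
    """A configuration value violates a stated bound."""


class InputError(XassocError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(XassocError, ValueError):
    """Input is structurally valid but statistically degenerate."""


class DesignError(XassocError, ValueError):
    """The analysis design is violated (e.g. a single-class cohort)."""


class LookupError_(XassocError, KeyError):
    """An identifier is not present in the container being queried."""


class PipelineOrderError(XassocError, RuntimeError):
    """A stage was invoked before a stage it depends on."""


class StratificationError(XassocError, ValueError):
    """Cross-validation folds cannot be stratified over both classes."""


class ContractError(XassocError, ValueError):
    """Two artifacts that must agree (e.g. feature panels) do not."""
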