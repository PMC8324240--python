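"""Exception hierarchy shared across the pipeline stages."""


class StrokeScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrokeScreenError):
    """Invalid generator / run configuration."""


class SchemaError(StrokeScreenError):
    """A required column or variable is missing from an input table."""


class EmptyDatasetError(StrokeScreenError):
    """A dataset construction rule produced no rows."""


class FitError(StrokeScreenError):
    """Model fitting failed (non-convergence, degenerate input)."""


class UndefinedMetricError(StrokeScreenError):
    """A metric is undefined on the given input (e.g. single-class AUROC)."""


class ContractViolationError(StrokeScreenError):
    """An operation received input violating its documented precondition."""
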