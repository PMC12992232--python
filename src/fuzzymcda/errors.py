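"""Exception hierarchy for fuzzymcda.

Every validation failure raises a subclass of :class:`FuzzymcdaError`, so
callers (and the CLI) can distinguish bad input from programming errors.
"""


class FuzzymcdaError(Exception):
    """Base class for all package-specific errors."""


class HierarchyError(FuzzymcdaError):
    """Malformed indicator hierarchy (duplicate id, orphan, level gap ...)."""


class PanelError(FuzzymcdaError):
    """Malformed expert-rating table (bad grade, unknown column ...)."""


class WeightError(FuzzymcdaError):
    """Invalid weight vector or judgment matrix."""


class EvaluationError(FuzzymcdaError):
    """Fuzzy-evaluation stage failure (missing membership row, bad vector)."""


class RobustnessError(FuzzymcdaError):
    """Sensitivity / bootstrap / reliability stage failure."""
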