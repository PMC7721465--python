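"""Exception hierarchy for the dove pipeline.

Every error the pipeline raises on bad input derives from :class:`DoveError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class DoveError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DoveError):
    """A file does not match its documented schema (missing columns, bad period)."""


class ValidationError(DoveError):
    """An input violates a domain invariant (negative rate, asymmetric adjacency...)."""


class SuppressionError(DoveError):
    """Suppressed-count imputation cannot proceed (state total suppressed, negative remainder)."""


class LeakageError(DoveError):
    """Training data at or after the target period reached a walk-forward fit."""


class MetricError(DoveError):
    """A score is undefined on the given inputs (all units excluded, zero totals)."""


class SchemaError(DoveError):
    """Feature names at predict time do not match the fitted model."""
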