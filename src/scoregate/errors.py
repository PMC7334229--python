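"""Exception hierarchy for scoregate.

All package errors derive from :class:`ScoregateError` so callers can catch
one base class; the CLI maps format/usage problems to exit status 2 and
validation/computation problems to exit status 1.
"""


class ScoregateError(Exception):
    """Base class for all scoregate errors."""


class FormatError(ScoregateError):
    """A file or payload does not match the expected on-disk format."""


class ValidationError(ScoregateError):
    """Data parsed fine but violates an invariant (range, uniqueness, ...)."""


class ConfigurationError(ScoregateError):
    """A simulation or goal configuration is invalid."""


class UndefinedRateError(ScoregateError):
    """A per-class rate was requested for a class with no ground-truth records."""


class QuantileUndefinedError(ScoregateError):
    """Score quantile requested for a class with no correct classifications."""


class SelectionError(ScoregateError):
    """Threshold selection failed (degenerate rate curve)."""


class TuningError(ScoregateError):
    """Threshold tuning failed (e.g. empty tuning table)."""


class DecisionError(ScoregateError):
    """The decision rule could not be applied to a record."""


class EvaluationError(ScoregateError):
    """Evaluation of a post-processed table failed."""


class UnsupportedModelError(ConfigurationError):
    """Operation only defined for a different score model."""
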