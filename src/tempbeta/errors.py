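"""Exception hierarchy for tempbeta.

All pipeline stages raise subclasses of :class:`TempbetaError` so callers
(and the CLI) can distinguish user-input problems from genuine bugs.
"""


class TempbetaError(Exception):
    """Base class for all tempbeta errors."""


class SchemaError(TempbetaError):
    """An input table is missing a required column or has an unusable dtype."""


class ValidationError(TempbetaError):
    """Row-level input problem: negative/NaN counts, duplicate keys, etc."""


class LookupError_(TempbetaError):
    """A requested meadow / predictor / column does not exist."""


class AlignmentError(TempbetaError):
    """Two vectors or matrices do not share the same species axis."""


class InsufficientTimesError(TempbetaError):
    """A dissimilarity statistic was requested for a series with T < 2."""


class UndefinedResultError(TempbetaError):
    """The statistic is undefined for this input (e.g. all times empty)."""


class InsufficientDataError(TempbetaError):
    """Too few observations for the requested estimate (CV, model fit)."""


class ConfigError(TempbetaError):
    """A run configuration references missing paths or inconsistent options."""
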