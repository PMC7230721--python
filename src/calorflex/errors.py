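"""Exception hierarchy shared across the pipeline."""


class CalorflexError(Exception):
    """Base class for all package errors."""


class FormatError(CalorflexError):
    """Malformed input file (missing columns, bad codings)."""


class EmptyTraceError(CalorflexError):
    """A trace with fewer than two valid samples."""


class OrderingError(CalorflexError):
    """Non-monotone time column in a trace."""


class EmptyEpochError(CalorflexError):
    """Epoching produced no populated epochs."""


class InsufficientDataError(CalorflexError):
    """Too few values for the requested statistic."""


class DomainError(CalorflexError):
    """Input outside the mathematical domain of an operation."""


class TooShortError(CalorflexError):
    """Recording shorter than discard + window span."""


class SingularFitError(CalorflexError):
    """Exactly collinear design matrix."""


class ConfigError(CalorflexError):
    """Invalid simulation or run configuration."""
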