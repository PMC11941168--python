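"""Exception hierarchy shared across dnbkit."""


class DNBKitError(Exception):
    """Base class for all dnbkit errors."""


class InvalidConfigurationError(DNBKitError, ValueError):
    """A parameter violates a precondition (sizes, signs, ranges)."""


class InvalidInputError(DNBKitError, ValueError):
    """A data object violates a structural contract (asymmetry, NaNs, ...)."""


class InsufficientSamplesError(DNBKitError, ValueError):
    """Too few samples for the requested statistic."""


class InsufficientStagesError(DNBKitError, ValueError):
    """Too few stages for stage-wise analysis."""


class UnstableSystemError(DNBKitError, ValueError):
    """Drift matrix has an eigenvalue with nonnegative real part; no
    stationary distribution exists."""


class UndefinedIndexError(DNBKitError, ValueError):
    """Composite index undefined (e.g. all member correlations masked)."""


class ParseError(DNBKitError, ValueError):
    """A TSV/JSON artifact failed validation; message names the offending
    line or column."""
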