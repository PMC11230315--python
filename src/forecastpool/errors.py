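"""Exception hierarchy.

Every error raised by this package derives from :class:`ForecastPoolError`
so callers (and the CLI) can catch one base class.
"""


class ForecastPoolError(Exception):
    """Base class for all package errors."""


class SchemaError(ForecastPoolError):
    """A required column is missing, misnamed, or structurally invalid."""


class DomainError(ForecastPoolError):
    """A value lies outside its permitted domain (e.g. quantile level > 1)."""


class MonotonicityError(ForecastPoolError):
    """A CDF group is not nondecreasing in its output_type_id order."""


class NormalizationError(ForecastPoolError):
    """A PMF group does not sum to one within tolerance."""


class DuplicateRowError(SchemaError):
    """Duplicate (model, task, output_type, output_type_id) rows."""


class CoverageError(ForecastPoolError):
    """A weight table does not cover every model in the prediction table."""


class DegenerateWeightsError(ForecastPoolError):
    """All weights in a stratum are zero, or a degenerate weighted median."""


class UnsupportedTypeError(ForecastPoolError):
    """An output type is not supported by the requested operation."""


class CapabilityError(ForecastPoolError):
    """A valid request combination the method cannot honour (e.g. weighted
    sample pooling)."""


class EmptyInputError(ForecastPoolError):
    """A group is empty after filtering."""


class IncompleteGroupError(ForecastPoolError):
    """Model membership differs across groups that must share components."""


class InsufficientDataError(ForecastPoolError):
    """Too few quantile pairs to fit a distribution."""


class SupportError(ForecastPoolError):
    """Values incompatible with the requested tail family's support."""


class DegenerateQuantilesError(ForecastPoolError):
    """Quantile pairs collapse to fewer than two distinct values."""


class GridMismatchError(ForecastPoolError):
    """Quantile level grids differ across models within a group."""


class GridError(ForecastPoolError):
    """A scoring grid is asymmetric or missing a required level."""


class JoinError(ForecastPoolError):
    """A forecast group cannot be matched to exactly one observation."""


class MissingBaselineError(ForecastPoolError):
    """The requested baseline model is absent from the score table."""


class ConfigurationError(ForecastPoolError):
    """Inconsistent or incomplete configuration of an operation."""


class ValidationError(ForecastPoolError):
    """A compound-task-ID set is inconsistent with the sample structure."""


class InsufficientSamplesError(ForecastPoolError):
    """A model has fewer sample indices than its subsetting target count."""


class HubSpecError(ForecastPoolError):
    """An invalid synthetic hub specification."""
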