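"""Exception hierarchy shared across pipeline stages."""


class RadpcrError(Exception):
    """Base class for all package errors."""


class FormatError(RadpcrError):
    """A file exists but its header or payload violates the expected format."""


class GeometryMismatchError(RadpcrError):
    """Image and mask geometries (shape/spacing/origin) disagree."""


class SamplingError(RadpcrError):
    """Seed sampling could not satisfy its contract (empty mask, boundary exhaustion)."""


class BalanceError(RadpcrError):
    """Cohort-level class balancing is impossible (single-class cohort)."""


class AggregationError(RadpcrError):
    """A subject has no patches to aggregate."""


class FitError(RadpcrError):
    """Model fitting preconditions violated (single class, degenerate data)."""


class SchemaError(RadpcrError):
    """Feature-column or subject-id mismatch between tables."""


class StatsError(RadpcrError):
    """Invalid inputs to a cohort statistic."""
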