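"""Exception hierarchy for the kwlpr package."""


class KwlprError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KwlprError):
    """A required column is missing or the schema mapping is inconsistent."""


class ParseError(KwlprError):
    """A cell could not be parsed as a number; names the row and column."""


class DataValidationError(KwlprError):
    """The table violates a dataset invariant (splits, missing values, sizes)."""


class ZeroVarianceError(KwlprError):
    """A training descriptor column is constant and cannot be auto-scaled."""


class EmptyNeighborhoodError(KwlprError):
    """All kernel weights at a query point are zero (compact kernel, small h)."""

    def __init__(self, message, query_ids=None):
        super().__init__(message)
        self.query_ids = list(query_ids) if query_ids is not None else []


class NumericalError(KwlprError):
    """A local solve remained singular after the ridge fallback."""


class UndefinedMetricError(KwlprError):
    """A metric denominator is degenerate (zero variance, constant vectors)."""


class UnsupportedMethodError(KwlprError):
    """The requested method does not apply to this problem shape."""


class RankDeficiencyError(KwlprError):
    """The global design matrix is rank deficient; names suspect columns."""
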