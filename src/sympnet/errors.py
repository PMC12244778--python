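"""Typed exceptions raised across the package."""


class SympnetError(Exception):
    """Base class for all package errors."""


class SchemaError(SympnetError):
    """Input table does not match the declared schema (unknown or missing columns)."""


class ValidationError(SympnetError):
    """Input data violates a documented contract (range, shape, emptiness)."""


class ZeroVarianceError(ValidationError):
    """A column is constant where variation is required."""


class SingularMatrixError(SympnetError):
    """A correlation matrix is singular where an inverse is required."""


class NotPositiveDefiniteError(SympnetError):
    """Requested partial correlations do not admit a positive-definite precision matrix."""

    def __init__(self, message, offending_edges=None):
        super().__init__(message)
        self.offending_edges = list(offending_edges or [])


class ConvergenceError(SympnetError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class AllSymptomsDroppedError(SympnetError):
    """The prevalence filter removed every symptom column."""


class RankDeficientError(SympnetError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, aliased_terms=None):
        super().__init__(message)
        self.aliased_terms = list(aliased_terms or [])


class GroupTooSmallError(SympnetError):
    """A comparison group has too few rows to estimate a network."""
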