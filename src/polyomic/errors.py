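"""Exception hierarchy for the polyomic package.

Each user-facing failure mode gets its own named class so callers (and the
CLI) can distinguish bad inputs from internal defects.
"""


class PolyomicError(Exception):
    """Base class for all polyomic errors."""


class DuplicateIDError(PolyomicError):
    """A feature table or metadata file contains repeated identifiers."""


class NonNumericValueError(PolyomicError):
    """A feature table cell could not be parsed as a number."""


class MetadataParseError(PolyomicError):
    """A metadata column is missing or contains an unknown category level."""


class MetadataConsistencyError(PolyomicError):
    """A participant carries more than one diagnosis across its samples."""


class AlignmentError(PolyomicError):
    """Feature table and metadata share no samples."""


class TransformStateError(PolyomicError):
    """An operation was applied to a table in the wrong transform state."""


class DomainError(PolyomicError):
    """A numeric transform was asked to evaluate outside its domain."""


class DegenerateGridError(PolyomicError):
    """The penalty grid collapsed (e.g. all features constant)."""


class StandardizationError(PolyomicError):
    """Standardization impossible (zero variance in the reference set)."""


class ScoringError(PolyomicError):
    """A score model references features absent from the table."""


class EvaluationError(PolyomicError):
    """Evaluation impossible (e.g. only one class present)."""


class CombinedModelError(PolyomicError):
    """The multi-omic combined model lacks the required score layers."""


class DesignError(PolyomicError):
    """A simulation design is internally infeasible."""


class SeparationWarning(UserWarning):
    """Logistic fit shows signs of (quasi-)complete separation."""


class CollinearityWarning(UserWarning):
    """Perfectly collinear columns detected in a regression design."""
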