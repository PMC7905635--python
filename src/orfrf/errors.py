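"""Exception hierarchy shared by all modules.

``OrfrfError`` is the base class; the CLI maps it to exit code 2
(data error) as opposed to usage errors (exit code 1).
"""


class OrfrfError(Exception):
    """Base class for all package errors."""


class FastaFormatError(OrfrfError):
    """Malformed or invalid FASTA input."""


class AnnotationError(OrfrfError):
    """Malformed annotation row or unresolvable interval reference."""


class FeatureDomainError(OrfrfError):
    """Input outside the domain of a feature operation (empty, non-triplet, N)."""


class LabelingError(OrfrfError):
    """Labeling cannot proceed (unknown seqid, single-class balance, ...)."""


class ModelError(OrfrfError):
    """Training/prediction contract violation (feature order, NaN, classes)."""


class ModelFormatError(ModelError):
    """Model file unreadable or of an incompatible format version."""


class EvaluationError(OrfrfError):
    """Invalid evaluation input (length mismatch, one-class AUC, ...)."""
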