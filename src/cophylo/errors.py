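"""Exception hierarchy shared across the package."""


class CophyloError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(CophyloError):
    """Malformed alignment (ragged rows, bad characters, duplicate ids)."""


class EmptyAlignmentError(AlignmentError):
    """Every sequence was removed by the length filter."""


class TreeError(CophyloError):
    """Malformed or unusable phylogeny."""


class TableError(CophyloError):
    """Malformed specimen table or association matrix."""


class DistanceError(CophyloError):
    """Distance matrix cannot be computed or is unusable."""


class ReconciliationError(CophyloError):
    """Reconciliation instance violates a precondition."""


class SeparationError(CophyloError):
    """Complete separation in a logistic fit: no finite estimate exists."""
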