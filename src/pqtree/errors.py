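"""Exception hierarchy for pqtree.

All package-specific failures derive from :class:`PQTreeError` so callers
can distinguish bad input from programming errors.
"""


class PQTreeError(Exception):
    """Base class for all pqtree errors."""


class AlignmentError(PQTreeError, ValueError):
    """Structurally invalid alignment (unequal rows, empty, duplicate ids)."""


class MatrixFormatError(PQTreeError, ValueError):
    """Malformed or asymmetric scoring-matrix file."""


class NewickError(PQTreeError, ValueError):
    """Unparseable Newick text."""


class TreeShapeError(PQTreeError, ValueError):
    """Tree violates a shape requirement (too few leaves, polytomy, leaf-set mismatch)."""
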