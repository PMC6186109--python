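"""Alignments, scoring matrices, and the column/alignment filters.

An :class:`Alignment` is an ordered set of equal-length labeled sequences
over a residue alphabet plus the gap symbol ``'-'``.  A
:class:`ScoringMatrix` is a symmetric map from letter pairs to numeric
scores, e.g. BLOSUM62 for proteins or the 4-letter identity matrix for
nucleotides.

Input conventions: sequences are upper-cased on read and ``'.'`` is
normalized to ``'-'``.  Letters that a scoring matrix does not know
(ambiguity codes such as X/B/Z/U in proteins or N in nucleotides) are
treated as gaps for scoring purposes, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, MatrixFormatError

GAP = "-"

__all__ = [
    "GAP",
    "Alignment",
    "ScoringMatrix",
    "ValidationReport",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_scoring_matrix",
    "identity_matrix",
    "blosum62",
    "load_matrix",
    "validate_alignment",
    "informative_columns",
    "drop_sparse_columns",
]


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment.

    Rows are strings of identical length over letters plus ``'-'``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not self.rows:
            raise AlignmentError("empty alignment")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("zero-length alignment rows")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"row {rid!r} has length {len(row)}, expected {length}"
                )
        if any(not rid for rid in self.ids):
            raise AlignmentError("empty sequence id")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def letter(self, i: int, c: int) -> str:
        """The letter of sequence *i* in column *c* (both 0-based)."""
        return self.rows[i][c]

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        """New alignment keeping the given columns, order preserved."""
        cols = list(cols)
        if not cols:
            raise AlignmentError("no columns left")
        rows = tuple("".join(row[c] for c in cols) for row in self.rows)
        return Alignment(self.ids, rows)

    def take_rows(self, idx: Sequence[int]) -> "Alignment":
        return Alignment(
            tuple(self.ids[i] for i in idx), tuple(self.rows[i] for i in idx)
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment.

    The id of each record is the header text up to the first whitespace;
    input order is preserved.  Raises :class:`AlignmentError` on unequal
    row lengths, duplicate ids or an empty file.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if not rows:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(tuple(ids), tuple(rows))


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for start in range(0, len(row), 70):
                fh.write(row[start : start + 70] + "\n")


@dataclass(frozen=True)
class ScoringMatrix:
    """A symmetric letter-pair scoring matrix S(a, b)."""

    alphabet: tuple[str, ...]
    values: np.ndarray  # square, symmetric; int64 when the source is integral
    name: str = ""
    _index: dict = field(repr=False, default=None, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        n = len(self.alphabet)
        if vals.shape != (n, n):
            raise MatrixFormatError("matrix shape does not match alphabet")
        if not np.array_equal(vals, vals.T):
            raise MatrixFormatError("scoring matrix is not symmetric")
        object.__setattr__(self, "values", vals)
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.alphabet)}
        )

    def score(self, a: str, b: str):
        return self.values[self._index[a], self._index[b]]

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    @property
    def is_integral(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    @property
    def min_diagonal(self):
        return self.values.diagonal().min()

    @property
    def min_off_diagonal(self):
        n = len(self.alphabet)
        if n < 2:
            return self.values.min()
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask].min()


def read_scoring_matrix(path: str | Path) -> ScoringMatrix:
    """Read a square scoring matrix in the standard text layout.

    The layout is the one used by common BLOSUM62 distributions: comment
    lines start with ``#``, then a header row of letters, then one labeled
    row per letter.  Asymmetric, incomplete or non-numeric input raises
    :class:`MatrixFormatError`.  Integer files are read as integers so that
    identity-matrix scoring stays exact.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixFormatError(f"no matrix content in {path}")
    header = lines[0].split()
    n = len(header)
    if n == 0:
        raise MatrixFormatError("empty header row")
    cells: list[list[str]] = []
    row_labels: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        row_labels.append(parts[0])
        cells.append(parts[1:])
    if row_labels != header:
        raise MatrixFormatError(
            f"row labels {row_labels} do not match header {header}"
        )
    flat = [tok for row in cells for tok in row]
    if any(len(row) != n for row in cells):
        raise MatrixFormatError("missing cell: row length does not match header")
    try:
        integral = all(_is_int_token(tok) for tok in flat)
        dtype = np.int64 if integral else np.float64
        values = np.array(
            [[int(t) if integral else float(t) for t in row] for row in cells],
            dtype=dtype,
        )
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.array_equal(values, values.T):
        raise MatrixFormatError(f"asymmetric matrix in {path}")
    return ScoringMatrix(tuple(header), values, name=path.stem)


def _is_int_token(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def identity_matrix(alphabet: str = "ACGT", name: str = "identity4") -> ScoringMatrix:
    """Diagonal matrix: 1 on matches, 0 otherwise (natural for nucleotides)."""
    n = len(alphabet)
    return ScoringMatrix(tuple(alphabet), np.eye(n, dtype=np.int64), name=name)


def blosum62() -> ScoringMatrix:
    """The BLOSUM62 matrix, via Biopython's bundled copy."""
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.load("BLOSUM62")
    alphabet = tuple(arr.alphabet)
    values = np.asarray(arr).astype(np.int64)  # BLOSUM62 entries are integers
    return ScoringMatrix(alphabet, values, name="BLOSUM62")


def load_matrix(spec: str) -> ScoringMatrix:
    """Load a matrix by built-in name (``blosum62``, ``identity4``) or file path."""
    key = spec.lower()
    if key == "blosum62":
        return blosum62()
    if key in ("identity4", "identity"):
        return identity_matrix()
    return read_scoring_matrix(spec)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    duplicate_pairs: tuple[tuple[str, str], ...]
    messages: tuple[str, ...]


def validate_alignment(aln: Alignment) -> ValidationReport:
    """Report identical-sequence pairs and too-small alignments.

    Alignments containing two or more identical sequences are unsuitable
    for inference (identical rows carry no quartet signal between them and
    such alignments are excluded from the reference benchmarks); fewer
    than four sequences leave quartets undefined.
    """
    messages: list[str] = []
    seen: dict[str, str] = {}
    dups: list[tuple[str, str]] = []
    for rid, row in zip(aln.ids, aln.rows):
        if row in seen:
            dups.append((seen[row], rid))
            messages.append(f"sequences {seen[row]!r} and {rid!r} are identical")
        else:
            seen[row] = rid
    if aln.n_seqs < 4:
        messages.append("fewer than four sequences")
    ok = not dups and aln.n_seqs >= 4
    return ValidationReport(ok, tuple(dups), tuple(messages))


def informative_columns(aln: Alignment) -> list[int]:
    """Indices of columns with at least two distinct non-gap letters.

    Columns with fewer than two distinct residues score zero for every
    quartet under every split and gap mode, so they are the only columns
    that can contribute to the tree score.
    """
    out = []
    for c in range(aln.length):
        letters = {row[c] for row in aln.rows if row[c] != GAP}
        if len(letters) >= 2:
            out.append(c)
    return out


def drop_sparse_columns(aln: Alignment, min_rows: int = 2) -> Alignment:
    """Remove columns represented by fewer than *min_rows* non-gap characters."""
    keep = [
        c
        for c in range(aln.length)
        if sum(row[c] != GAP for row in aln.rows) >= min_rows
    ]
    if not keep:
        raise AlignmentError("all columns removed by sparsity filter")
    if len(keep) == aln.length:
        return aln
    return aln.take_columns(keep)


def matrix_codes(aln: Alignment, matrix: ScoringMatrix) -> np.ndarray:
    """Encode rows as indices into the matrix alphabet; gaps/unknowns -> len(alphabet).

    Letters absent from the matrix alphabet are treated as gaps for scoring,
    with a warning naming the letters involved.
    """
    index = {a: i for i, a in enumerate(matrix.alphabet)}
    gap_code = len(matrix.alphabet)
    unknown: set[str] = set()
    codes = np.empty((aln.n_seqs, aln.length), dtype=np.int16)
    for i, row in enumerate(aln.rows):
        for c, letter in enumerate(row):
            if letter == GAP:
                codes[i, c] = gap_code
            elif letter in index:
                codes[i, c] = index[letter]
            else:
                unknown.add(letter)
                codes[i, c] = gap_code
    if unknown:
        warnings.warn(
            f"letters {sorted(unknown)} absent from matrix {matrix.name!r}; "
            "treated as gaps for scoring",
            stacklevel=2,
        )
    return codes
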