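"""The position-quartet (PQ) tree criterion.

For an alignment column *c* and a quartet of sequences split by the tree
into sides {i,j} | {k,l}, the column's support for that split is

    Q_cq = max(S(a_ic, a_jc) - X_cq, 0) + max(S(a_kc, a_lc) - X_cq, 0)

where S is a symmetric scoring matrix and X_cq is the maximum matrix
value over the four cross-split letter pairs.  A generalization rewards
doubly supported quartets: when both sides exceed X_cq the contribution
becomes alpha * (S_side1 + S_side2 - 2 * X_cq) for a positive weight
alpha (alpha = 1 recovers the base form).

The tree score Q sums Q_cq over all columns and quartets; the alignment
maximum Q^m sums, per column and quartet, the best of the three possible
splits; the normalized score S = Q / Q^m lies in [0, 1] and is comparable
across alignments of different sizes.

Scores are accumulated per quartet in a :class:`QuartetTable` (three sums
per quartet, one per split), which is the search engine's working state:
any tree on the same leaves can then be scored by table lookups alone.
Accumulation is exact integer arithmetic whenever the matrix and alpha
are integral (BLOSUM62, identity).

Gap handling (``gap_mode``):

* ``ignore`` (default): a (column, quartet) pair is admitted only if all
  four letters are residues.
* ``gap_as_letter``: the gap is an additional alphabet letter; everything
  is admitted.
* ``at_most_one_gap``: admitted iff the four letters contain <= 1 gap.

In the two non-default modes the matrix is extended with a gap row whose
defaults are the matrix's minimum diagonal (gap-gap) and minimum
off-diagonal (gap-residue) values; both are overridable in
:class:`ScoreConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .errors import AlignmentError, TreeShapeError
from .seqdata import GAP, Alignment, ScoringMatrix, matrix_codes
from .treekit import UnrootedTree

__all__ = [
    "ScoreConfig",
    "QuartetTable",
    "ScoreResult",
    "cross_max",
    "quartet_column_score",
    "build_quartet_table",
    "tree_score",
    "tree_score_direct",
    "quartet_ranks",
    "all_quartets",
]

GAP_MODES = ("ignore", "gap_as_letter", "at_most_one_gap")


class _OpCounter:
    """Counts elementary quartet-score operations (cost model, not time).

    Table construction contributes one unit per (column, quartet) pair;
    every later table lookup contributes one unit per quartet touched.
    Used to verify the documented scaling laws without relying on
    wall-clock measurements.
    """

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)

    def reset(self) -> None:
        self.count = 0


OP_COUNTER = _OpCounter()


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the PQ criterion."""

    matrix: ScoringMatrix
    alpha: float = 1.0
    gap_mode: str = "ignore"
    gap_gap_score: float | None = None
    gap_residue_score: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.gap_mode not in GAP_MODES:
            raise ValueError(f"gap_mode must be one of {GAP_MODES}")

    @property
    def is_integral(self) -> bool:
        return self.matrix.is_integral and float(self.alpha).is_integer()

    def extended_values(self) -> np.ndarray:
        """Matrix extended with the gap letter as the last row/column."""
        vals = self.matrix.values
        n = vals.shape[0]
        gg = self.gap_gap_score if self.gap_gap_score is not None else self.matrix.min_diagonal
        gr = (
            self.gap_residue_score
            if self.gap_residue_score is not None
            else self.matrix.min_off_diagonal
        )
        dtype = vals.dtype if self.matrix.is_integral and float(gg).is_integer() and float(gr).is_integer() else np.float64
        ext = np.zeros((n + 1, n + 1), dtype=dtype)
        ext[:n, :n] = vals
        ext[n, :n] = gr
        ext[:n, n] = gr
        ext[n, n] = gg
        return ext


@dataclass(frozen=True)
class ScoreResult:
    """Tree score Q, alignment maximum Q^m, normalized score S = Q / Q^m."""

    q: float
    q_max: float
    s: float


# ------------------------------------------------------------- scalar scoring

_SIDE_PAIRS = {
    # pairing p groups positions (0, 1+p); the other two positions form side 2
    0: ((0, 1), (2, 3)),
    1: ((0, 2), (1, 3)),
    2: ((0, 3), (1, 2)),
}


def _sides(split: int) -> tuple[tuple[int, int], tuple[int, int]]:
    try:
        return _SIDE_PAIRS[split]
    except KeyError:
        raise ValueError("split must be 0, 1 or 2") from None


def _pair_score(a: str, b: str, config: ScoreConfig):
    matrix = config.matrix
    if a != GAP and b != GAP and a in matrix and b in matrix:
        return matrix.score(a, b)
    if config.gap_mode == "ignore":
        raise ValueError("gapped letters are not scoreable in gap_mode='ignore'")
    ext = config.extended_values()
    g = len(matrix.alphabet)
    ia = matrix._index.get(a, g) if a != GAP else g
    ib = matrix._index.get(b, g) if b != GAP else g
    return ext[ia, ib]


def cross_max(letters: Sequence[str], split: int, matrix: ScoringMatrix):
    """X_cq: the maximum matrix value across the split of the quartet.

    ``letters`` holds the four column letters in quartet order; ``split``
    selects the pairing (0 pairs letters[0] with letters[1], etc.).
    """
    (s1a, s1b), (s2a, s2b) = _sides(split)
    cfg = ScoreConfig(matrix)
    return max(
        _pair_score(letters[s1a], letters[s2a], cfg),
        _pair_score(letters[s1a], letters[s2b], cfg),
        _pair_score(letters[s1b], letters[s2a], cfg),
        _pair_score(letters[s1b], letters[s2b], cfg),
    )


def quartet_column_score(letters: Sequence[str], split: int, config: ScoreConfig):
    """The PQ score of one column for one quartet under one split.

    Scalar reference implementation: with side scores s1, s2 and cross
    maximum X, returns 0 / (s1 - X) / (s2 - X) / alpha*(s1 + s2 - 2X)
    according to which sides exceed X; always >= 0.  With alpha = 1 this
    is max(s1 - X, 0) + max(s2 - X, 0).
    """
    if len(letters) != 4:
        raise ValueError("need exactly four letters")
    if config.gap_mode == "ignore" and any(l == GAP for l in letters):
        raise ValueError("column not admitted under gap_mode='ignore'")
    if config.gap_mode == "at_most_one_gap" and sum(l == GAP for l in letters) > 1:
        raise ValueError("column not admitted under gap_mode='at_most_one_gap'")
    (s1a, s1b), (s2a, s2b) = _sides(split)
    s1 = _pair_score(letters[s1a], letters[s1b], config)
    s2 = _pair_score(letters[s2a], letters[s2b], config)
    x = max(
        _pair_score(letters[s1a], letters[s2a], config),
        _pair_score(letters[s1a], letters[s2b], config),
        _pair_score(letters[s1b], letters[s2a], config),
        _pair_score(letters[s1b], letters[s2b], config),
    )
    d1 = s1 - x
    d2 = s2 - x
    if d1 > 0 and d2 > 0:
        value = config.alpha * (d1 + d2)
        return int(value) if config.is_integral else value
    return max(d1, 0) + max(d2, 0)


# ----------------------------------------------------------- quartet indexing


def all_quartets(n: int) -> np.ndarray:
    """All C(n, 4) sorted quartets of [0, n) in lexicographic order."""
    return np.array(list(combinations(range(n), 4)), dtype=np.int64).reshape(-1, 4)


def quartet_ranks(n: int, quads: np.ndarray) -> np.ndarray:
    """Lexicographic rank of sorted quartets (combinatorial number system).

    ``quads`` is an (m, 4) array with strictly increasing rows.
    """
    quads = np.asarray(quads)
    c4 = np.array([comb(x, 4) for x in range(n + 1)], dtype=np.int64)
    c3 = np.array([comb(x, 3) for x in range(n + 1)], dtype=np.int64)
    c2 = np.array([comb(x, 2) for x in range(n + 1)], dtype=np.int64)
    i, j, k, l = quads[..., 0], quads[..., 1], quads[..., 2], quads[..., 3]
    return (
        (c4[n] - c4[n - i])
        + (c3[n - 1 - i] - c3[n - j])
        + (c2[n - 1 - j] - c2[n - k])
        + (l - k - 1)
    )


# ------------------------------------------------------------------ the table


@dataclass
class QuartetTable:
    """Column-summed PQ scores for every quartet and each of its three splits.

    ``scores[r, p]`` is the sum over admitted columns of the PQ score of
    quartet rank *r* (lexicographic order of sorted index quartets) under
    pairing *p* (p pairs the smallest index with the (1+p)-th smallest).
    ``q_max_total`` is Q^m: the per-column, per-quartet best-of-three,
    summed.
    """

    ids: tuple[str, ...]
    scores: np.ndarray  # (C(n,4), 3)
    q_max_total: float
    config: ScoreConfig
    _quartets: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_quartets(self) -> int:
        return self.scores.shape[0]

    @property
    def quartets(self) -> np.ndarray:
        if self._quartets is None:
            self._quartets = all_quartets(self.n_seqs)
        return self._quartets

    @property
    def score_tol(self):
        """Comparison tolerance for 'score improved' tests."""
        return 0 if np.issubdtype(self.scores.dtype, np.integer) else 1e-9

    def dump(self) -> str:
        """Plain tabular text dump (debugging aid): i j k l s0 s1 s2."""
        lines = ["i\tj\tk\tl\tP0\tP1\tP2"]
        for (i, j, k, l), row in zip(self.quartets, self.scores):
            lines.append(f"{i}\t{j}\t{k}\t{l}\t{row[0]}\t{row[1]}\t{row[2]}")
        return "\n".join(lines)


def _eq2(s1, s2, x, alpha):
    """Vectorized generalized PQ score."""
    d1 = s1 - x
    d2 = s2 - x
    out = np.where(d1 > 0, d1, 0) + np.where(d2 > 0, d2, 0)
    if alpha != 1:
        both = (d1 > 0) & (d2 > 0)
        scaled = alpha * (d1 + d2)
        if np.issubdtype(out.dtype, np.integer) and float(alpha).is_integer():
            scaled = scaled.astype(out.dtype)
        out = np.where(both, scaled, out)
    return out


def build_quartet_table(
    aln: Alignment, config: ScoreConfig, chunk_size: int = 8192
) -> QuartetTable:
    """Accumulate per-quartet, per-split column sums for the whole alignment.

    Cost grows as Theta(N^4 * L); the resulting C(N,4) x 3 table then
    supports scoring any tree without revisiting the alignment.
    """
    n = aln.n_seqs
    if n < 4:
        raise AlignmentError("quartet scoring needs at least four sequences")
    codes = matrix_codes(aln, config.matrix)
    gap_code = len(config.matrix.alphabet)
    ext = config.extended_values()
    if config.is_integral and not np.issubdtype(ext.dtype, np.integer):
        ext = ext.astype(np.float64)
    dtype = np.int64 if config.is_integral and np.issubdtype(ext.dtype, np.integer) else np.float64
    quads = all_quartets(n)
    nq = quads.shape[0]
    scores = np.zeros((nq, 3), dtype=dtype)
    q_max_total = dtype(0)
    alpha = config.alpha
    any_admitted = False
    for start in range(0, nq, chunk_size):
        block = quads[start : start + chunk_size]
        OP_COUNTER.add(block.shape[0] * aln.length)
        a = codes[block[:, 0]]
        b = codes[block[:, 1]]
        c = codes[block[:, 2]]
        d = codes[block[:, 3]]
        s_ab = ext[a, b]
        s_ac = ext[a, c]
        s_ad = ext[a, d]
        s_bc = ext[b, c]
        s_bd = ext[b, d]
        s_cd = ext[c, d]
        gaps = (
            (a == gap_code).astype(np.int8)
            + (b == gap_code)
            + (c == gap_code)
            + (d == gap_code)
        )
        if config.gap_mode == "ignore":
            adm = gaps == 0
        elif config.gap_mode == "at_most_one_gap":
            adm = gaps <= 1
        else:
            adm = np.ones_like(gaps, dtype=bool)
        q0 = _eq2(s_ab, s_cd, np.maximum(np.maximum(s_ac, s_ad), np.maximum(s_bc, s_bd)), alpha)
        q1 = _eq2(s_ac, s_bd, np.maximum(np.maximum(s_ab, s_ad), np.maximum(s_bc, s_cd)), alpha)
        q2 = _eq2(s_ad, s_bc, np.maximum(np.maximum(s_ab, s_ac), np.maximum(s_bd, s_cd)), alpha)
        q0 = np.where(adm, q0, 0)
        q1 = np.where(adm, q1, 0)
        q2 = np.where(adm, q2, 0)
        any_admitted = any_admitted or bool(adm.any())
        scores[start : start + chunk_size, 0] = q0.sum(axis=1)
        scores[start : start + chunk_size, 1] = q1.sum(axis=1)
        scores[start : start + chunk_size, 2] = q2.sum(axis=1)
        q_max_total += np.maximum(np.maximum(q0, q1), q2).sum()
    if not any_admitted:
        warnings.warn(
            "no (column, quartet) pair admitted under the gap mode; "
            "all quartet scores are zero",
            stacklevel=2,
        )
    if dtype == np.int64:
        q_max_total = int(q_max_total)
    else:
        q_max_total = float(q_max_total)
    return QuartetTable(tuple(aln.ids), scores, q_max_total, config)


# ----------------------------------------------------------------- tree score


def _check_leaves(table: QuartetTable, tree: UnrootedTree) -> None:
    if set(tree.leaf_labels) != set(table.ids):
        missing = set(table.ids) ^ set(tree.leaf_labels)
        raise TreeShapeError(f"tree/alignment leaf sets differ on {sorted(missing)}")


def induced_pairings(table: QuartetTable, tree: UnrootedTree) -> np.ndarray:
    """Tree-induced pairing (0/1/2) for every quartet, in table rank order.

    Uses the four-point condition on unit-branch-length leaf distances:
    the induced pairing is the unique one whose within-side distance sum
    is strictly smallest.
    """
    d = tree.leaf_dist_matrix(table.ids)
    q = table.quartets
    s0 = d[q[:, 0], q[:, 1]] + d[q[:, 2], q[:, 3]]
    s1 = d[q[:, 0], q[:, 2]] + d[q[:, 1], q[:, 3]]
    s2 = d[q[:, 0], q[:, 3]] + d[q[:, 1], q[:, 2]]
    return np.argmin(np.stack([s0, s1, s2], axis=1), axis=1)


def tree_score(table: QuartetTable, tree: UnrootedTree) -> ScoreResult:
    """Score a binary tree against the table: Q, Q^m and S = Q / Q^m."""
    _check_leaves(table, tree)
    tree.require_binary()
    OP_COUNTER.add(table.n_quartets)
    pairings = induced_pairings(table, tree)
    q = table.scores[np.arange(table.n_quartets), pairings].sum()
    q = int(q) if np.issubdtype(table.scores.dtype, np.integer) else float(q)
    q_max = table.q_max_total
    s = q / q_max if q_max > 0 else 0.0
    return ScoreResult(q, q_max, s)


def tree_score_direct(aln: Alignment, tree: UnrootedTree, config: ScoreConfig) -> ScoreResult:
    """Brute-force tree score straight from the alignment (no table).

    A deliberately independent double loop over columns and quartets using
    the scalar column score; used to cross-check the table pipeline.  Slow
    (pure Python); intended for small inputs.
    """
    if set(tree.leaf_labels) != set(aln.ids):
        raise TreeShapeError("tree/alignment leaf sets differ")
    tree.require_binary()
    known = set(config.matrix.alphabet)
    q_total = 0
    q_max_total = 0
    for idx_quartet in combinations(range(aln.n_seqs), 4):
        labels = [aln.ids[i] for i in idx_quartet]
        realized = tree.induced_quartet_split(labels)
        for c in range(aln.length):
            letters = [
                aln.letter(i, c) if aln.letter(i, c) in known else GAP
                for i in idx_quartet
            ]
            n_gaps = sum(l == GAP for l in letters)
            if config.gap_mode == "ignore" and n_gaps > 0:
                continue
            if config.gap_mode == "at_most_one_gap" and n_gaps > 1:
                continue
            per_split = [
                quartet_column_score(letters, p, config) for p in range(3)
            ]
            q_total += per_split[realized]
            q_max_total += max(per_split)
    s = q_total / q_max_total if q_max_total > 0 else 0.0
    return ScoreResult(q_total, q_max_total, s)
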