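"""Evaluation statistics for comparing reconstruction methods.

Per-alignment normalized Robinson-Foulds distances to a reference
(species) tree are the raw material; on top of them sit the paired sign
test, quartile-based good/bad counts, correlations, and the long-branch
attraction (LBA) diagnostic that looks for an erroneous split grouping
two lone fast-evolving taxa.

Sign-test convention: the exact binomial tail of the larger count,
P(X >= max(m, n) | m + n trials, p = 1/2).  This one-sided form is the
one that reproduces the published benchmark p-values (e.g. 13/0 ->
1.2e-4 = 0.5^13, 17/2 -> 3.6e-4); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqdata import Alignment
from .treekit import UnrootedTree, parse_newick, rf_distance_normalized
from .errors import TreeShapeError

__all__ = [
    "MethodRun",
    "sign_test",
    "pairwise_compare",
    "quartile_counts",
    "pearson",
    "has_lba_split",
    "lba_paired_counts",
    "median_length",
    "load_tree_dir",
    "distance_table",
]


@dataclass(frozen=True)
class MethodRun:
    """One method's per-alignment distances to the reference tree."""

    method: str
    distances: tuple[float, ...]
    scores: tuple[float, ...] | None = None
    lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if any(not (0 <= d <= 1) for d in self.distances):
            raise ValueError("distances must lie in [0, 1]")


def sign_test(m: int, n: int) -> float:
    """Exact one-sided sign test of m vs n (tail of the larger count)."""
    if m < 0 or n < 0:
        raise ValueError("counts must be nonnegative")
    if m + n == 0:
        raise ValueError("sign test needs at least one untied pair")
    return float(
        stats.binomtest(max(m, n), m + n, 0.5, alternative="greater").pvalue
    )


def pairwise_compare(
    d_a: Sequence[float], d_b: Sequence[float]
) -> tuple[int, int, float]:
    """Paired comparison of two methods' distances.

    Returns (better, worse, p): the number of alignments where method A
    is strictly closer to the reference than method B, the number where
    it is strictly farther, and the sign-test p-value (1.0 when every
    pair is tied).
    """
    if len(d_a) != len(d_b):
        raise ValueError("paired distance lists differ in length")
    better = sum(a < b for a, b in zip(d_a, d_b))
    worse = sum(a > b for a, b in zip(d_a, d_b))
    p = 1.0 if better + worse == 0 else sign_test(better, worse)
    return better, worse, p


def quartile_counts(
    reference_dists: Sequence[float], method_dists: Sequence[float]
) -> tuple[int, int, float, float]:
    """Counts of relatively good and bad reconstructions.

    Thresholds are the lower and upper quartiles (inclusive
    linear-interpolation quantiles) of the reference method's distances;
    good/bad counts use strict inequalities, so when the distance takes
    only a few values the counts can fall below a quarter of the list.
    """
    if len(reference_dists) == 0 or len(method_dists) == 0:
        raise ValueError("empty distance list")
    q1 = float(np.quantile(reference_dists, 0.25))
    q3 = float(np.quantile(reference_dists, 0.75))
    n_good = int(sum(d < q1 for d in method_dists))
    n_bad = int(sum(d > q3 for d in method_dists))
    return n_good, n_bad, q1, q3


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length lists of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance")
    return float(stats.pearsonr(x, y).statistic)


def has_lba_split(tree: UnrootedTree, lone_pair: Sequence[str]) -> bool:
    """Whether the tree contains the split {lone_pair} | {everything else}.

    This is the long-branch-attraction signature: two lone, rapidly
    evolving taxa pulled together into a clade of their own.
    """
    a, b = lone_pair
    labels = set(tree.leaf_labels)
    for lab in (a, b):
        if lab not in labels:
            raise TreeShapeError(f"label {lab!r} not in tree")
    pair = frozenset((a, b))
    smallest = min(labels)
    target = pair if smallest not in pair else frozenset(labels - pair)
    return target in tree.nontrivial_splits()


def lba_paired_counts(
    runs_a: Sequence[tuple[bool, bool]],
    runs_b: Sequence[tuple[bool, bool]],
) -> tuple[int, int]:
    """Paired LBA counts over orthologous groups and two tests.

    m counts groups where method A never shows the LBA split in either
    test while method B shows it at least once; n counts the opposite.
    """
    if len(runs_a) != len(runs_b):
        raise ValueError("methods cover different group counts")
    m = n = 0
    for flags_a, flags_b in zip(runs_a, runs_b):
        a_any, b_any = any(flags_a), any(flags_b)
        if not a_any and b_any:
            m += 1
        elif a_any and not b_any:
            n += 1
    return m, n


def median_length(alignments: Sequence[Alignment]) -> int:
    """Median column count (lower median for even cardinality)."""
    if not alignments:
        raise ValueError("empty alignment set")
    lengths = sorted(a.length for a in alignments)
    return lengths[(len(lengths) - 1) // 2]


# ----------------------------------------------------------------- reporting


def load_tree_dir(path: str | Path, min_leaves: int = 4) -> dict[str, UnrootedTree]:
    """Read every Newick file of a directory, keyed by file stem."""
    path = Path(path)
    out = {}
    for f in sorted(path.iterdir()):
        if f.suffix.lower() in (".nwk", ".newick", ".tre", ".tree", ".txt"):
            out[f.stem] = parse_newick(f.read_text(), min_leaves=min_leaves)
    if not out:
        raise FileNotFoundError(f"no Newick files under {path}")
    return out


def distance_table(
    reference: Mapping[str, UnrootedTree],
    methods: Mapping[str, Mapping[str, UnrootedTree]],
) -> pd.DataFrame:
    """Per-alignment RF distances of each method to the reference trees.

    Rows are alignments (the intersection of names present everywhere),
    columns are methods.  Reference trees with more leaves than a method
    tree are restricted to the method tree's leaf set first, mirroring
    how species trees are compared with subset reconstructions.
    """
    names = set(reference)
    for trees in methods.values():
        names &= set(trees)
    if not names:
        raise ValueError("no alignment names shared by reference and methods")
    rows = {}
    for name in sorted(names):
        ref = reference[name]
        row = {}
        for method, trees in methods.items():
            t = trees[name]
            r = ref
            if set(r.leaf_labels) != set(t.leaf_labels):
                r = r.restrict(t.leaf_labels)
            row[method] = rf_distance_normalized(r, t)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
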