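"""Synthetic trees and alignments with a known true topology.

The generator is a deliberately simple stand-in for full sequence-evolution
simulators: a uniformly random binary unrooted topology, a root sequence
drawn uniformly over the alphabet, and independent per-site point
substitutions on every branch (each mutated site moves to a uniformly
chosen *different* letter, Jukes-Cantor style).  Optional gaps are whole
columns gapped in a random subset of rows, enough to exercise the three
gap modes.  The goal is test signal with a known truth, not realism.

Also provided is the rRNA-style subsampling used for nucleotide
benchmarks: a random 15-row subset and a random block of 300-800 columns
from a large reference alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, TreeShapeError
from .seqdata import GAP, Alignment, write_fasta_alignment
from .treekit import UnrootedTree

__all__ = [
    "EvolveParams",
    "random_topology",
    "evolve_alignment",
    "subsample_alignment",
    "write_fixtures",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class EvolveParams:
    """Conditions of a simulated alignment.

    ``subst_prob`` is the per-branch, per-site substitution probability;
    a (low, high) pair draws one probability per branch uniformly.
    ``gap_prob`` is the probability that a column receives gaps, and
    ``gap_row_prob`` the per-row chance of being gapped in such a column.
    """

    length: int = 500
    subst_prob: float | tuple[float, float] = 0.05
    alphabet: str = DNA_ALPHABET
    gap_prob: float = 0.0
    gap_row_prob: float = 0.25
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        lo, hi = self._prob_range()
        if not (0 <= lo <= hi <= 1):
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if not (0 <= self.gap_prob <= 1 and 0 <= self.gap_row_prob <= 1):
            raise ValueError("gap probabilities must lie in [0, 1]")

    def _prob_range(self) -> tuple[float, float]:
        if isinstance(self.subst_prob, tuple):
            return self.subst_prob
        return (self.subst_prob, self.subst_prob)


def random_topology(
    n_leaves: int,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> UnrootedTree:
    """Uniformly random binary unrooted topology by sequential attachment.

    Each new leaf is hung on a uniformly chosen edge of the growing tree,
    which makes every one of the (2n-5)!! topologies equally likely.
    """
    if n_leaves < 4:
        raise TreeShapeError("need at least four leaves")
    if labels is None:
        labels = [f"s{i + 1}" for i in range(n_leaves)]
    labels = list(labels)
    if len(labels) != n_leaves:
        raise ValueError("label count does not match n_leaves")
    tree = UnrootedTree.star3(labels[:3])
    for pos in range(3, n_leaves):
        edges = tree.edges()
        edge = edges[int(rng.integers(len(edges)))]
        tree.attach_leaf_inplace(edge, labels[pos])
    return tree


def evolve_alignment(
    tree: UnrootedTree,
    params: EvolveParams,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve sequences down the tree by independent point substitutions.

    The root of the simulation is the internal vertex next to the first
    leaf; each branch mutates each site independently with the branch's
    substitution probability.  Rows are labeled by the leaf labels and
    returned in sorted label order.  If the draw produces duplicate rows
    (possible at low noise) it is repeated up to ``max_redraws`` times,
    with a warning when duplicates survive.
    """
    for attempt in range(params.max_redraws + 1):
        aln = _evolve_once(tree, params, rng)
        if len(set(aln.rows)) == aln.n_seqs:
            return aln
    warnings.warn(
        "duplicate sequences persist after redraws (noise too low "
        "for the alignment length)",
        stacklevel=2,
    )
    return aln


def _evolve_once(
    tree: UnrootedTree, params: EvolveParams, rng: np.random.Generator
) -> Alignment:
    alphabet = params.alphabet
    n_letters = len(alphabet)
    length = params.length
    lo, hi = params._prob_range()
    labels = tree.leaf_labels
    root = tree._adj[tree.node_of(labels[0])][0]
    seqs: dict[int, np.ndarray] = {
        root: rng.integers(0, n_letters, size=length)
    }
    stack = [(root, None)]
    leaf_rows: dict[str, np.ndarray] = {}
    while stack:
        node, prev = stack.pop()
        seq = seqs.pop(node)
        if node in tree._leaf:
            leaf_rows[tree._leaf[node]] = seq
        for nb in sorted(tree._adj[node]):
            if nb == prev:
                continue
            p = lo if lo == hi else float(rng.uniform(lo, hi))
            child = seq.copy()
            mask = rng.random(length) < p
            k = int(mask.sum())
            if k:
                # jump to a uniformly chosen *different* letter
                child[mask] = (child[mask] + rng.integers(1, n_letters, size=k)) % n_letters
            seqs[nb] = child
            stack.append((nb, node))
    rows = []
    for lab in labels:
        rows.append("".join(alphabet[c] for c in leaf_rows[lab]))
    if params.gap_prob > 0:
        rows = _insert_gaps(rows, params, rng)
    return Alignment(tuple(labels), tuple(rows))


def _insert_gaps(rows: list[str], params: EvolveParams, rng: np.random.Generator) -> list[str]:
    n = len(rows)
    length = len(rows[0])
    grid = np.array([list(r) for r in rows])
    for c in range(length):
        if rng.random() < params.gap_prob:
            mask = rng.random(n) < params.gap_row_prob
            if not mask.any():
                mask[int(rng.integers(n))] = True
            grid[mask, c] = GAP
    return ["".join(row) for row in grid]


def subsample_alignment(
    aln: Alignment,
    rng: np.random.Generator,
    n_rows: int = 15,
    col_range: tuple[int, int] = (300, 800),
) -> Alignment:
    """Random rRNA-style subalignment: *n_rows* rows and N columns.

    N is drawn uniformly from ``col_range`` (inclusive); rows and columns
    are sampled without replacement with column order preserved.  The
    matching reference tree is the species tree restricted to the chosen
    rows.
    """
    lo, hi = col_range
    if aln.n_seqs < n_rows:
        raise AlignmentError(f"need at least {n_rows} rows, have {aln.n_seqs}")
    if aln.length < hi:
        raise AlignmentError(f"need at least {hi} columns, have {aln.length}")
    n_cols = int(rng.integers(lo, hi + 1))
    row_idx = sorted(rng.choice(aln.n_seqs, size=n_rows, replace=False).tolist())
    col_idx = sorted(rng.choice(aln.length, size=n_cols, replace=False).tolist())
    return aln.take_rows(row_idx).take_columns(col_idx)


def write_fixtures(
    out_dir: str | Path,
    n_sets: int,
    n_leaves: int,
    params: EvolveParams,
    seed: int,
) -> list[tuple[Path, Path]]:
    """Write FASTA + true-tree Newick pairs plus a manifest of parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pairs = []
    manifest = [
        "name\tn_leaves\tlength\tsubst_prob\tgap_prob\tseed",
    ]
    for k in range(n_sets):
        tree = random_topology(n_leaves, rng)
        aln = evolve_alignment(tree, params, rng)
        fasta = out_dir / f"aln_{k:03d}.fasta"
        nwk = out_dir / f"tree_{k:03d}.nwk"
        write_fasta_alignment(aln, fasta)
        nwk.write_text(tree.to_newick() + "\n")
        manifest.append(
            f"aln_{k:03d}\t{n_leaves}\t{params.length}\t{params.subst_prob}"
            f"\t{params.gap_prob}\t{seed}"
        )
        pairs.append((fasta, nwk))
    (out_dir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return pairs
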