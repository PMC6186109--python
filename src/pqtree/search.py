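"""Heuristic search for a high-scoring tree under the PQ criterion.

Five strategies are provided: single stepwise addition, multiple
(randomly shuffled) stepwise addition, NNI hill climbing, NNI Monte
Carlo (simulated annealing), and SPR hill climbing.  The default
pipeline -- tenfold stepwise addition followed by NNI hill climbing --
is what :func:`infer` runs.

Scoring is incremental wherever the neighborhood structure allows it:

* stepwise addition evaluates a candidate attachment branch by summing
  only the quartets that contain the newly added leaf;
* NNI moves are scored by a delta restricted to quartets with one leaf
  in each of the four subtrees around the edited edge;
* SPR candidates are rescored by the full vectorized table evaluation.

Ties are broken everywhere in favor of the first candidate in
deterministic traversal order, and all randomness flows through a single
numpy Generator, so runs are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import exp
from typing import Iterable, Sequence

import numpy as np

from .errors import TreeShapeError
from .pqscore import (
    OP_COUNTER,
    QuartetTable,
    ScoreConfig,
    ScoreResult,
    build_quartet_table,
    quartet_ranks,
    tree_score,
)
from .seqdata import Alignment, validate_alignment
from .treekit import UnrootedTree

__all__ = [
    "AnnealSchedule",
    "SearchConfig",
    "MCStats",
    "stepwise_addition",
    "multiple_stepwise",
    "nni_neighbors",
    "nni_score_delta",
    "nni_hill_climb",
    "nni_monte_carlo",
    "accept_probability",
    "spr_hill_climb",
    "exhaustive_search",
    "infer",
]

STRATEGIES = ("sa1", "sa_multi", "nni_hc", "nni_mc", "spr_hc")


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature schedule of the NNI Monte Carlo search.

    The temperature starts at ``t_ini`` and is reduced by
    ``t_ini / n_steps_divisor`` after every proposal, so the search stops
    after exactly ``n_steps_divisor`` proposals.  Only the ratio
    ``k / t`` enters the acceptance probability.
    """

    t_ini: float = 1000.0
    k: float = 12_000_000.0
    n_steps_divisor: int = 1000

    def __post_init__(self) -> None:
        if not (self.t_ini > 0 and self.k > 0 and self.n_steps_divisor >= 1):
            raise ValueError("invalid annealing schedule")


@dataclass(frozen=True)
class SearchConfig:
    """Which strategy to run and with what randomness."""

    strategy: str = "nni_hc"
    n_starts: int = 10
    rng_seed: int = 0
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class MCStats:
    proposals: int
    accepted: int
    best_q: float


# ------------------------------------------------------------------ helpers


def _label_index(table: QuartetTable) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(table.ids)}


def _pairing_from_partner(srt: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pairing index of sorted quartets given the pairing (x,y) | (z,w).

    All arguments are equal-length index arrays; ``srt`` is the (m, 4)
    sorted quartet array built from the same rows.
    """
    m = srt[:, 0]
    partner = np.where(m == x, y, np.where(m == y, x, np.where(m == z, w, z)))
    return (srt[:, 2] == partner) * 1 + (srt[:, 3] == partner) * 2


def nni_score_delta(
    table: QuartetTable, tree: UnrootedTree, edge: tuple[int, int], choice: int
):
    """Score change of one NNI, touching only the quartets it can affect.

    Only quartets with one leaf in each of the four subtrees around the
    edited edge change their induced pairing; everything else cancels.
    """
    _, (la, lb, lc, ld) = tree.edge_context(edge)
    idx = _label_index(table)
    a = np.array([idx[x] for x in la], dtype=np.int64)
    b = np.array([idx[x] for x in lb], dtype=np.int64)
    c = np.array([idx[x] for x in lc], dtype=np.int64)
    d = np.array([idx[x] for x in ld], dtype=np.int64)
    if choice == 1:
        c, d = d, c  # swapping B with D pairs a with the other flank
    # quartets (a, b, c, d), one from each subtree; old sides {a,b} | {c,d},
    # new sides (after swapping the B and C subtrees) {a,c} | {b,d}
    aa, bb, cc, dd = np.meshgrid(a, b, c, d, indexing="ij")
    quad = np.stack(
        [aa.ravel(), bb.ravel(), cc.ravel(), dd.ravel()], axis=1
    )
    srt = np.sort(quad, axis=1)
    ranks = quartet_ranks(table.n_seqs, srt)
    OP_COUNTER.add(2 * ranks.size)
    p_old = _pairing_from_partner(srt, quad[:, 0], quad[:, 1], quad[:, 2], quad[:, 3])
    p_new = _pairing_from_partner(srt, quad[:, 0], quad[:, 2], quad[:, 1], quad[:, 3])
    delta = table.scores[ranks, p_new].sum() - table.scores[ranks, p_old].sum()
    return int(delta) if np.issubdtype(table.scores.dtype, np.integer) else float(delta)


# ---------------------------------------------------------- stepwise addition


def stepwise_addition(table: QuartetTable, order: Sequence[int]) -> UnrootedTree:
    """Build a tree by inserting sequences one at a time at the best branch.

    The first four sequences are placed on the best of the three possible
    quartet topologies; each later sequence is attached on the branch of
    the current tree that maximizes the score gain over the quartets
    containing it.  Ties go to the first branch in traversal order.
    """
    n = table.n_seqs
    order = list(order)
    if sorted(order) != list(range(n)):
        raise ValueError("order must be a permutation of all sequence indices")
    labels = table.ids
    first4 = order[:4]
    srt4 = sorted(first4)
    rank = int(quartet_ranks(n, np.array([srt4]))[0])
    best_p = int(np.argmax(table.scores[rank]))  # first max wins
    tree = UnrootedTree.from_quartet(
        [labels[i] for i in srt4], best_p, node_ids=srt4, internal_start=n
    )
    for x in order[4:]:
        _attach_best_inplace(table, tree, x)
    return tree


def _attach_best_inplace(table: QuartetTable, tree: UnrootedTree, x: int) -> None:
    """Attach global sequence *x* on the branch with maximal score gain."""
    n = table.n_seqs
    labels = table.ids
    idx = _label_index(table)
    current = sorted(idx[lab] for lab in tree.leaf_labels)
    m = len(current)
    cur_labels = [labels[i] for i in current]
    # node -> distance maps, one per present leaf (in `current` order)
    dist_maps = tree._node_dists_to_leaves(cur_labels)
    leaf_nodes = [tree.node_of(lab) for lab in cur_labels]
    d_ss = np.array(
        [[dist_maps[i][leaf_nodes[j]] for j in range(m)] for i in range(m)],
        dtype=np.float64,
    )
    triplets = np.array(list(combinations(range(m), 3)), dtype=np.int64).reshape(-1, 3)
    t1, t2, t3 = triplets[:, 0], triplets[:, 1], triplets[:, 2]
    g1, g2, g3 = (
        np.asarray(current)[t1],
        np.asarray(current)[t2],
        np.asarray(current)[t3],
    )
    quad = np.stack([g1, g2, g3, np.full_like(g1, x)], axis=1)
    srt = np.sort(quad, axis=1)
    ranks = quartet_ranks(n, srt)
    # pairing index for each possible partner of x among the triplet
    pair_if = np.stack(
        [
            _pairing_from_partner(srt, quad[:, 3], quad[:, j], quad[:, (j + 1) % 3], quad[:, (j + 2) % 3])
            for j in range(3)
        ],
        axis=1,
    )
    base23 = d_ss[t2, t3]
    base13 = d_ss[t1, t3]
    base12 = d_ss[t1, t2]
    rows = np.arange(ranks.shape[0])
    best_gain = None
    best_edge = None
    for p, q in tree.edges():
        dw = np.array(
            [min(dist_maps[i][p], dist_maps[i][q]) for i in range(m)],
            dtype=np.float64,
        )  # distance from the subdivision point, up to a constant
        s_partner1 = dw[t1] + base23
        s_partner2 = dw[t2] + base13
        s_partner3 = dw[t3] + base12
        partner = np.argmin(np.stack([s_partner1, s_partner2, s_partner3], axis=1), axis=1)
        pairing = pair_if[rows, partner]
        OP_COUNTER.add(ranks.size)
        gain = table.scores[ranks, pairing].sum()
        if best_gain is None or gain > best_gain:
            best_gain = gain
            best_edge = (p, q)
    tree.attach_leaf_inplace(best_edge, labels[x], node_id=x)


def multiple_stepwise(
    table: QuartetTable,
    n_starts: int,
    rng: np.random.Generator,
    orders: Iterable[Sequence[int]] | None = None,
) -> UnrootedTree:
    """Best tree over repeated stepwise addition with shuffled input orders.

    ``orders`` overrides the random shuffles (used for reproducing a
    single fixed-order run); ties keep the first tree attained.
    """
    if orders is None:
        orders = [rng.permutation(table.n_seqs).tolist() for _ in range(n_starts)]
    best_tree = None
    best_q = None
    tol = table.score_tol
    for order in orders:
        t = stepwise_addition(table, order)
        q = tree_score(table, t).q
        if best_q is None or q > best_q + tol:
            best_tree, best_q = t, q
    return best_tree


# -------------------------------------------------------------- NNI searches


def nni_neighbors(tree: UnrootedTree) -> list[UnrootedTree]:
    """All 2*(n-3) nearest-neighbor interchanges of a binary tree."""
    return tree.nni_neighbors()


def nni_hill_climb(table: QuartetTable, start: UnrootedTree) -> UnrootedTree:
    """First-improvement NNI ascent to a local optimum.

    Scans neighbors in canonical edge order, moves to the first strictly
    improving one and restarts the scan; stops when no NNI improves.
    """
    tree = start.copy()
    tol = table.score_tol
    improved = True
    while improved:
        improved = False
        for edge in tree.internal_edges_canonical():
            for choice in (0, 1):
                delta = nni_score_delta(table, tree, edge, choice)
                if delta > tol:
                    tree.nni_inplace(edge, choice)
                    improved = True
                    break
            if improved:
                break
    return tree


def accept_probability(q_new, q_old, t: float, k: float) -> float:
    """Downhill acceptance probability exp((k/t) * (q_new - q_old) / q_old).

    Defined as 0 when the current score is 0 (no relative scale exists).
    """
    if q_old <= 0:
        return 0.0
    return exp((k / t) * (q_new - q_old) / q_old)


def nni_monte_carlo(
    table: QuartetTable,
    start: UnrootedTree,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | None = None,
    return_stats: bool = False,
):
    """Simulated-annealing NNI search.

    Proposals walk the canonical NNI list of the current tree; a strict
    improvement is always taken, a strictly worse tree is taken with
    probability exp((K/T) * dQ/Q_old), and equal scores are rejected.
    The temperature drops by t_ini / n_steps_divisor after every proposal
    (accepted or not) and the search stops when it reaches zero.  The
    best tree among all visited is returned.
    """
    schedule = schedule or AnnealSchedule()
    rng = rng if rng is not None else np.random.default_rng(0)
    tree = start.copy()
    q = tree_score(table, tree).q
    best_tree, best_q = tree.copy(), q
    tol = table.score_tol
    temp = schedule.t_ini
    decrement = schedule.t_ini / schedule.n_steps_divisor
    proposals = 0
    accepted = 0
    moves = [(e, c) for e in tree.internal_edges_canonical() for c in (0, 1)]
    pos = 0
    while temp > 0:
        if pos >= len(moves):
            pos = 0
        edge, choice = moves[pos]
        delta = nni_score_delta(table, tree, edge, choice)
        take = False
        if delta > tol:
            take = True
        elif delta < -tol:
            p = accept_probability(q + delta, q, temp, schedule.k)
            take = bool(rng.random() < p)
        if take:
            tree.nni_inplace(edge, choice)
            q += delta
            accepted += 1
            if q > best_q + tol:
                best_tree, best_q = tree.copy(), q
            moves = [(e, c) for e in tree.internal_edges_canonical() for c in (0, 1)]
            pos = 0
        else:
            pos += 1
        proposals += 1
        temp -= decrement
        if temp <= 1e-12:  # guard against float drift in the decrement
            temp = 0.0
    if return_stats:
        return best_tree, MCStats(proposals, accepted, best_q)
    return best_tree


# -------------------------------------------------------------- SPR search


def spr_hill_climb(table: QuartetTable, start: UnrootedTree) -> UnrootedTree:
    """First-improvement ascent over the full SPR neighborhood.

    The NNI neighborhood is contained in the SPR neighborhood, so the
    result is also NNI-optimal.
    """
    tree = start.copy()
    q = tree_score(table, tree).q
    tol = table.score_tol
    improved = True
    while improved:
        improved = False
        for cand in tree.spr_neighbors():
            qc = tree_score(table, cand).q
            if qc > q + tol:
                tree, q = cand, qc
                improved = True
                break
    return tree


# ------------------------------------------------------------- brute force


def _all_topologies(labels: Sequence[str]) -> list[UnrootedTree]:
    """Every binary unrooted topology on the given labels ((2n-5)!! trees)."""
    if len(labels) < 3:
        raise TreeShapeError("need at least three labels")
    trees = [UnrootedTree.star3(labels[:3])]
    for pos in range(3, len(labels)):
        nxt = []
        for t in trees:
            for edge in t.edges():
                nxt.append(t.attach_leaf(edge, labels[pos]))
        trees = nxt
    return trees


def exhaustive_search(table: QuartetTable) -> tuple[UnrootedTree, ScoreResult]:
    """Score every topology and return the first-found best.

    Factorially expensive; intended as an oracle for n <= 8 or so.
    """
    best = None
    best_res = None
    tol = table.score_tol
    for t in _all_topologies(list(table.ids)):
        res = tree_score(table, t)
        if best_res is None or res.q > best_res.q + tol:
            best, best_res = t, res
    return best, best_res


# -------------------------------------------------------------------- infer


def infer(
    aln: Alignment,
    score_cfg: ScoreConfig,
    search_cfg: SearchConfig | None = None,
) -> tuple[UnrootedTree, ScoreResult]:
    """Reconstruct a tree for an alignment.

    Builds the quartet table once, then runs the configured strategy.
    ``sa1`` is a single stepwise addition in input order; ``sa_multi``
    repeats with shuffled orders; the NNI/SPR refinements start from the
    best of ten stepwise-addition runs (the default pipeline being that
    start followed by NNI hill climbing).
    """
    search_cfg = search_cfg or SearchConfig()
    report = validate_alignment(aln)
    if aln.n_seqs < 4:
        raise TreeShapeError("inference needs at least four sequences")
    if not report.ok:
        import warnings

        warnings.warn("; ".join(report.messages), stacklevel=2)
    table = build_quartet_table(aln, score_cfg)
    rng = np.random.default_rng(search_cfg.rng_seed)
    strategy = search_cfg.strategy
    if strategy == "sa1":
        tree = stepwise_addition(table, range(table.n_seqs))
    elif strategy == "sa_multi":
        tree = multiple_stepwise(table, search_cfg.n_starts, rng)
    else:
        start = multiple_stepwise(table, 10, rng)
        if strategy == "nni_hc":
            tree = nni_hill_climb(table, start)
        elif strategy == "nni_mc":
            tree = nni_monte_carlo(table, start, search_cfg.anneal, rng)
        else:  # spr_hc
            tree = spr_hill_climb(table, start)
    return tree, tree_score(table, tree)
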