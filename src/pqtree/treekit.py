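"""Unrooted leaf-labeled trees: Newick I/O, splits, RF distance, consensus.

The central object is :class:`UnrootedTree`, a leaf-labeled tree stored as
an adjacency map.  Binary here means every internal vertex has degree 3,
which gives ``n_leaves - 2`` internal vertices and ``n_leaves - 3``
nontrivial edges.  Polytomies are tolerated on parse (consensus input) but
rejected by scoring and search.

Splits are stored canonically as the side that does **not** contain the
globally smallest leaf label, as a frozenset of labels.

Newick reading is delegated to dendropy (branch lengths and internal
labels are tolerated and discarded); writing is our own deterministic
serializer: topology only, rooted for serialization at the internal vertex
adjacent to the lexicographically smallest leaf, children ordered by their
smallest descendant label.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from typing import Iterable, Sequence

import numpy as np

from .errors import NewickError, TreeShapeError

__all__ = [
    "UnrootedTree",
    "parse_newick",
    "write_newick",
    "nontrivial_splits",
    "induced_quartet_split",
    "rf_distance_normalized",
    "restrict_tree",
    "majority_rule_extended_consensus",
]


class UnrootedTree:
    """Unrooted leaf-labeled tree over an adjacency map.

    Node ids are opaque integers; leaves carry string labels.  Mutating
    helpers (suffixed ``_inplace``) exist for the search engine; public
    operations return new trees.
    """

    __slots__ = ("_adj", "_leaf", "_node_of", "_next_id")

    def __init__(
        self,
        adj: dict[int, list[int]],
        leaf: dict[int, str],
    ) -> None:
        self._adj = adj
        self._leaf = leaf
        self._node_of = {lab: node for node, lab in leaf.items()}
        if len(self._node_of) != len(leaf):
            raise TreeShapeError("duplicate leaf labels")
        self._next_id = max(adj, default=-1) + 1

    # ------------------------------------------------------------------ basics

    @property
    def n_leaves(self) -> int:
        return len(self._leaf)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self._leaf.values()))

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    @property
    def is_binary(self) -> bool:
        return all(
            len(nbrs) in (1, 3) for nbrs in self._adj.values()
        ) and self.n_leaves >= 3

    def require_binary(self) -> None:
        if not self.is_binary:
            raise TreeShapeError("tree is not binary (polytomy present)")

    def copy(self) -> "UnrootedTree":
        t = object.__new__(UnrootedTree)
        t._adj = {k: list(v) for k, v in self._adj.items()}
        t._leaf = dict(self._leaf)
        t._node_of = dict(self._node_of)
        t._next_id = self._next_id
        return t

    def node_of(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise TreeShapeError(f"label {label!r} not in tree") from None

    def edges(self) -> list[tuple[int, int]]:
        """All edges as (u, v) with u < v, in deterministic node-id order."""
        out = []
        for u in self._adj:
            for v in self._adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    # ------------------------------------------------------------ construction

    @classmethod
    def star3(cls, labels: Sequence[str], node_ids: Sequence[int] | None = None) -> "UnrootedTree":
        """The unique tree on three leaves."""
        if len(labels) != 3:
            raise TreeShapeError("star3 needs exactly three labels")
        ids = list(node_ids) if node_ids is not None else [0, 1, 2]
        center = max(ids) + 1
        adj = {center: list(ids)}
        for i in ids:
            adj[i] = [center]
        return cls(adj, dict(zip(ids, labels)))

    @classmethod
    def from_quartet(
        cls,
        labels: Sequence[str],
        pairing: int,
        node_ids: Sequence[int] | None = None,
        internal_start: int | None = None,
    ) -> "UnrootedTree":
        """Four-leaf tree realizing one of the three pairings of *labels*.

        ``pairing`` pairs labels[0] with labels[1 + pairing]; e.g. pairing 0
        gives ({labels[0],labels[1]} | {labels[2],labels[3]}).
        ``internal_start`` reserves id space below it for leaves added later.
        """
        if len(labels) != 4:
            raise TreeShapeError("from_quartet needs exactly four labels")
        ids = list(node_ids) if node_ids is not None else [0, 1, 2, 3]
        partner = 1 + pairing
        others = [i for i in (1, 2, 3) if i != partner]
        u = max(max(ids) + 1, internal_start or 0)
        v = u + 1
        adj: dict[int, list[int]] = {
            u: [ids[0], ids[partner], v],
            v: [ids[others[0]], ids[others[1]], u],
        }
        for pos in range(4):
            adj[ids[pos]] = [u if pos in (0, partner) else v]
        return cls(adj, dict(zip(ids, labels)))

    def attach_leaf_inplace(self, edge: tuple[int, int], label: str, node_id: int | None = None) -> int:
        """Subdivide *edge* with a new vertex and hang a new leaf off it."""
        u, v = edge
        if v not in self._adj[u]:
            raise TreeShapeError(f"no edge {edge}")
        leaf_id = node_id if node_id is not None else self._next_id
        mid = max(leaf_id, self._next_id) + 1
        self._adj[u][self._adj[u].index(v)] = mid
        self._adj[v][self._adj[v].index(u)] = mid
        self._adj[mid] = [u, v, leaf_id]
        self._adj[leaf_id] = [mid]
        self._leaf[leaf_id] = label
        self._node_of[label] = leaf_id
        self._next_id = mid + 1
        return leaf_id

    def attach_leaf(self, edge: tuple[int, int], label: str) -> "UnrootedTree":
        t = self.copy()
        t.attach_leaf_inplace(edge, label)
        return t

    def _suppress_degree_two(self) -> None:
        for node in [n for n in list(self._adj) if len(self._adj[n]) == 2 and n not in self._leaf]:
            a, b = self._adj[node]
            self._adj[a][self._adj[a].index(node)] = b
            self._adj[b][self._adj[b].index(node)] = a
            del self._adj[node]

    # ----------------------------------------------------------------- queries

    def _leafset_away(self, start: int, away_from: int) -> list[str]:
        """Leaf labels of the subtree containing *start* after cutting (start, away_from)."""
        out = []
        stack = [(start, away_from)]
        while stack:
            node, prev = stack.pop()
            if node in self._leaf:
                out.append(self._leaf[node])
            for nb in self._adj[node]:
                if nb != prev:
                    stack.append((nb, node))
        return out

    def nontrivial_splits(self) -> set[frozenset[str]]:
        """Canonical nontrivial bipartitions (n_leaves - 3 of them when binary)."""
        labels = self.leaf_labels
        if len(labels) < 4:
            return set()
        smallest = labels[0]
        all_labels = frozenset(labels)
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            if u in self._leaf or v in self._leaf:
                continue
            side = frozenset(self._leafset_away(u, v))
            if smallest in side:
                side = all_labels - side
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        return out

    def leaf_dist_matrix(self, order: Sequence[str]) -> np.ndarray:
        """Topological (unit-branch) leaf-to-leaf distances in the given label order."""
        nodes = self._node_dists_to_leaves(order)
        leaf_nodes = [self._node_of[lab] for lab in order]
        return np.array([[nodes[i][ln] for ln in leaf_nodes] for i in range(len(order))])

    def _node_dists_to_leaves(self, order: Sequence[str]) -> list[dict[int, int]]:
        """BFS distance maps node -> distance, one per leaf in *order*."""
        out = []
        for lab in order:
            src = self.node_of(lab)
            dist = {src: 0}
            dq = deque([src])
            while dq:
                node = dq.popleft()
                for nb in self._adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        dq.append(nb)
            out.append(dist)
        return out

    def induced_quartet_split(self, quartet: Sequence[str]) -> int:
        """Which pairing of the four labels the tree induces.

        Returns 0, 1 or 2: pairing *p* groups ``quartet[0]`` with
        ``quartet[1 + p]``.  The result is the unique pairing separated by
        some edge of the tree.
        """
        if len(quartet) != 4 or len(set(quartet)) != 4:
            raise TreeShapeError("quartet must hold four distinct labels")
        nodes = [self.node_of(lab) for lab in quartet]
        d = {}
        for a in range(4):
            dist = {nodes[a]: 0}
            dq = deque([nodes[a]])
            while dq:
                node = dq.popleft()
                for nb in self._adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        dq.append(nb)
            for b in range(a + 1, 4):
                d[(a, b)] = dist[nodes[b]]
        sums = (
            d[(0, 1)] + d[(2, 3)],
            d[(0, 2)] + d[(1, 3)],
            d[(0, 3)] + d[(1, 2)],
        )
        return int(np.argmin(sums))

    # --------------------------------------------------------------- rearrange

    def internal_edges_canonical(self) -> list[tuple[int, int]]:
        """Internal (nontrivial) edges ordered by their canonical split key."""
        labels = self.leaf_labels
        smallest = labels[0] if labels else ""
        all_labels = frozenset(labels)
        keyed = []
        for u, v in self.edges():
            if u in self._leaf or v in self._leaf:
                continue
            side = frozenset(self._leafset_away(u, v))
            if smallest in side:
                side = all_labels - side
            keyed.append((tuple(sorted(side)), (u, v)))
        keyed.sort()
        return [edge for _, edge in keyed]

    def _ordered_flank_neighbors(self, u: int, v: int) -> list[int]:
        """Neighbors of u other than v, ordered by smallest leaf label of their subtree."""
        nbrs = [x for x in self._adj[u] if x != v]
        return sorted(nbrs, key=lambda x: min(self._leafset_away(x, u)))

    def edge_context(self, edge: tuple[int, int]):
        """The four subtrees around an internal edge.

        Returns ``((a1, a2, b1, b2), (A, B, C, D))`` where a1/a2 flank u,
        b1/b2 flank v (each pair ordered by smallest subtree label) and
        A-D are the corresponding leaf-label lists.  NNI choice 0 swaps the
        B and C subtrees, choice 1 swaps B and D.
        """
        u, v = edge
        a1, a2 = self._ordered_flank_neighbors(u, v)
        b1, b2 = self._ordered_flank_neighbors(v, u)
        return (
            (a1, a2, b1, b2),
            (
                self._leafset_away(a1, u),
                self._leafset_away(a2, u),
                self._leafset_away(b1, v),
                self._leafset_away(b2, v),
            ),
        )

    def nni_inplace(self, edge: tuple[int, int], choice: int) -> None:
        """Apply one nearest-neighbor interchange across an internal edge."""
        u, v = edge
        (a1, a2, b1, b2), _ = self.edge_context(edge)
        other = b1 if choice == 0 else b2
        self._adj[u][self._adj[u].index(a2)] = other
        self._adj[other][self._adj[other].index(v)] = u
        self._adj[v][self._adj[v].index(other)] = a2
        self._adj[a2][self._adj[a2].index(u)] = v

    def nni(self, edge: tuple[int, int], choice: int) -> "UnrootedTree":
        t = self.copy()
        t.nni_inplace(edge, choice)
        return t

    def nni_neighbors(self) -> list["UnrootedTree"]:
        """The 2*(n_leaves - 3) NNI rearrangements, in canonical order."""
        self.require_binary()
        out = []
        for edge in self.internal_edges_canonical():
            for choice in (0, 1):
                out.append(self.nni(edge, choice))
        return out

    def spr_neighbors(self) -> list["UnrootedTree"]:
        """Distinct subtree-prune-and-regraft rearrangements.

        Every subtree (each directed edge defines one) is pruned and
        regrafted onto every other edge of the remaining tree.  Results
        are deduplicated by split set; the input topology is excluded.
        The NNI neighborhood is a subset of this one.
        """
        self.require_binary()
        base = frozenset(self.nontrivial_splits())
        seen = {base}
        out = []
        for u, v in self.edges():
            for root, anchor in ((u, v), (v, u)):
                cand_list = self._spr_moves(root, anchor)
                for cand in cand_list:
                    key = frozenset(cand.nontrivial_splits())
                    if key not in seen:
                        seen.add(key)
                        out.append(cand)
        return out

    def _spr_moves(self, root: int, anchor: int) -> list["UnrootedTree"]:
        """Prune the subtree at *root* (cut edge root-anchor), regraft everywhere."""
        if anchor in self._leaf:
            return []  # remaining side would be a bare leaf
        pruned_leaves = set(self._leafset_away(root, anchor))
        if len(pruned_leaves) > self.n_leaves - 3:
            return []  # remaining tree too small to offer a distinct edge
        base = self.copy()
        # cut the edge and suppress the degree-2 anchor
        base._adj[root].remove(anchor)
        base._adj[anchor].remove(root)
        x, y = base._adj[anchor]
        base._adj[x][base._adj[x].index(anchor)] = y
        base._adj[y][base._adj[y].index(anchor)] = x
        del base._adj[anchor]
        merged = (min(x, y), max(x, y))
        subtree_nodes = set()
        stack = [(root, None)]
        while stack:
            node, prev = stack.pop()
            subtree_nodes.add(node)
            for nb in base._adj[node]:
                if nb != prev:
                    stack.append((nb, node))
        out = []
        for p, q in base.edges():
            if p in subtree_nodes or q in subtree_nodes:
                continue
            if (p, q) == merged:
                continue  # recreates the original topology
            t = base.copy()
            mid = t._next_id
            t._adj[p][t._adj[p].index(q)] = mid
            t._adj[q][t._adj[q].index(p)] = mid
            t._adj[mid] = [p, q, root]
            t._adj[root].append(mid)
            t._next_id = mid + 1
            out.append(t)
        return out

    # --------------------------------------------------------------- restrict

    def restrict(self, labels: Iterable[str]) -> "UnrootedTree":
        """Prune to a leaf subset; suppress the resulting degree-2 vertices."""
        keep = set(labels)
        unknown = keep - set(self._leaf.values())
        if unknown:
            raise TreeShapeError(f"labels not in tree: {sorted(unknown)}")
        if len(keep) < 4:
            raise TreeShapeError("restriction needs at least four labels")
        t = self.copy()
        drop = [n for n, lab in t._leaf.items() if lab not in keep]
        for node in drop:
            lab = t._leaf.pop(node)
            del t._node_of[lab]
            (nb,) = t._adj.pop(node)
            t._adj[nb].remove(node)
        # iteratively clean up degree-1 internal stubs and degree-2 vertices
        changed = True
        while changed:
            changed = False
            for node in list(t._adj):
                if node in t._leaf:
                    continue
                deg = len(t._adj[node])
                if deg == 1:
                    (nb,) = t._adj.pop(node)
                    t._adj[nb].remove(node)
                    changed = True
                elif deg == 2:
                    a, b = t._adj.pop(node)
                    t._adj[a][t._adj[a].index(node)] = b
                    t._adj[b][t._adj[b].index(node)] = a
                    changed = True
        return t

    # ------------------------------------------------------------------ output

    def _subtree_min_label(self, node: int, prev: int, memo: dict) -> str:
        key = (node, prev)
        if key in memo:
            return memo[key]
        if node in self._leaf:
            memo[key] = self._leaf[node]
            return self._leaf[node]
        best = min(
            self._subtree_min_label(nb, node, memo)
            for nb in self._adj[node]
            if nb != prev
        )
        memo[key] = best
        return best

    def to_newick(self) -> str:
        """Deterministic topology-only Newick string (trailing ';', no lengths)."""
        if self.n_leaves == 0:
            raise TreeShapeError("empty tree")
        if self.n_leaves == 1:
            return f"{next(iter(self._leaf.values()))};"
        smallest_node = self.node_of(self.leaf_labels[0])
        root = self._adj[smallest_node][0]
        if root in self._leaf:  # two-leaf tree
            return f"({self.leaf_labels[0]},{self.leaf_labels[1]});"
        memo: dict = {}

        def render(node: int, prev: int) -> str:
            if node in self._leaf:
                return self._leaf[node]
            children = sorted(
                (nb for nb in self._adj[node] if nb != prev),
                key=lambda nb: self._subtree_min_label(nb, node, memo),
            )
            return "(" + ",".join(render(ch, node) for ch in children) + ")"

        children = sorted(
            self._adj[root], key=lambda nb: self._subtree_min_label(nb, root, memo)
        )
        return "(" + ",".join(render(ch, root) for ch in children) + ");"

    def __repr__(self) -> str:
        return f"UnrootedTree(n_leaves={self.n_leaves})"


# ---------------------------------------------------------------------- I/O


def parse_newick(text: str, min_leaves: int = 4) -> UnrootedTree:
    """Parse Newick text into an :class:`UnrootedTree`.

    Branch lengths and internal node labels are tolerated and discarded.
    A rooted (bifurcating-at-root) input is unrooted by suppressing the
    degree-2 root.  Fewer than *min_leaves* leaves is a shape error
    (quartet scoring needs at least four).
    """
    import dendropy

    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    counter = itertools.count()
    node_id: dict = {}
    adj: dict[int, list[int]] = {}
    leaf: dict[int, str] = {}
    for nd in dt.preorder_node_iter():
        node_id[nd] = next(counter)
    for nd in dt.preorder_node_iter():
        i = node_id[nd]
        adj.setdefault(i, [])
        for ch in nd.child_nodes():
            j = node_id[ch]
            adj[i].append(j)
            adj.setdefault(j, []).append(i)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("leaf without a label")
            if nd.taxon.label in leaf.values():
                raise NewickError(f"duplicate leaf label {nd.taxon.label!r}")
            leaf[i] = nd.taxon.label
    if len(leaf) < min_leaves:
        raise TreeShapeError(
            f"tree has {len(leaf)} leaves; at least {min_leaves} required"
        )
    tree = UnrootedTree(adj, leaf)
    tree._suppress_degree_two()
    return tree


def write_newick(tree: UnrootedTree) -> str:
    return tree.to_newick()


# ----------------------------------------------------------------- operations


def nontrivial_splits(tree: UnrootedTree) -> set[frozenset[str]]:
    return tree.nontrivial_splits()


def induced_quartet_split(tree: UnrootedTree, quartet: Sequence[str]) -> int:
    return tree.induced_quartet_split(quartet)


def rf_distance_normalized(t1: UnrootedTree, t2: UnrootedTree) -> float:
    """Normalized Robinson-Foulds distance between two binary trees.

    The number of splits present in exactly one of the trees, divided by
    the total split count of both trees; 0 for identical topologies, 1
    when no nontrivial split is shared.
    """
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        raise TreeShapeError("leaf sets differ")
    t1.require_binary()
    t2.require_binary()
    s1 = t1.nontrivial_splits()
    s2 = t2.nontrivial_splits()
    total = len(s1) + len(s2)
    if total == 0:
        return 0.0
    return len(s1 ^ s2) / total


def restrict_tree(tree: UnrootedTree, labels: Iterable[str]) -> UnrootedTree:
    return tree.restrict(labels)


def _compatible(a: frozenset, b: frozenset) -> bool:
    # canonical sides both exclude the smallest label, so their complements
    # always intersect; compatibility reduces to nested-or-disjoint
    return a <= b or b <= a or not (a & b)


def majority_rule_extended_consensus(trees: Sequence[UnrootedTree]) -> UnrootedTree:
    """Greedy (majority-rule extended) consensus of binary trees.

    Splits occurring in more than half of the trees are accepted first;
    remaining splits are then added in order of decreasing frequency when
    compatible with everything already accepted (ties broken by the
    lexicographically smallest canonical split).  If the accepted splits
    do not fully resolve the tree, the remaining polytomies are resolved
    deterministically by pairing children with the smallest labels first.
    """
    if not trees:
        raise TreeShapeError("consensus of zero trees")
    labels = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != labels:
            raise TreeShapeError("consensus requires identical leaf sets")
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.nontrivial_splits())
    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    accepted: list[frozenset[str]] = []
    for split, _count in ordered:
        if all(_compatible(split, other) for other in accepted):
            accepted.append(split)
    return _tree_from_splits(labels, accepted)


def _tree_from_splits(
    labels: Sequence[str], splits: Iterable[frozenset[str]]
) -> UnrootedTree:
    """Build a binary tree whose split set contains the given laminar family."""
    labels = sorted(labels)
    clades = sorted(set(splits), key=len)
    counter = itertools.count()
    leaf_node = {lab: next(counter) for lab in labels}
    root_children: dict[object, list] = {None: []}
    clade_node = {}
    # assign each clade/leaf to its smallest enclosing clade (clades are laminar)
    parent_of_clade = {}
    for i, cl in enumerate(clades):
        parent_of_clade[cl] = None
        for bigger in clades[i + 1 :]:
            if cl < bigger:
                parent_of_clade[cl] = bigger
                break
    children: dict[object, list] = {None: [], **{cl: [] for cl in clades}}
    for cl in clades:
        children[parent_of_clade[cl]].append(cl)
    covered: dict[str, object] = {}
    for cl in clades:  # smallest first, so first hit is the tightest clade
        for lab in cl:
            if lab not in covered:
                covered[lab] = cl
    for lab in labels:
        children[covered.get(lab)].append(lab)

    adj: dict[int, list[int]] = {i: [] for i in leaf_node.values()}
    leaf = {node: lab for lab, node in leaf_node.items()}

    def build(group) -> int:
        """Return the node id rooting this group, resolving polytomies."""
        kids = []
        for ch in children[group]:
            if isinstance(ch, frozenset):
                kids.append(build(ch))
            else:
                kids.append(leaf_node[ch])
        kids.sort(key=lambda nd: _min_label_below(nd))
        target = 3 if group is None else 2
        while len(kids) > target:
            a = kids.pop(0)
            b = kids.pop(0)
            joint = next(counter)
            adj[joint] = [a, b]
            adj[a].append(joint)
            adj[b].append(joint)
            kids.append(joint)
            kids.sort(key=lambda nd: _min_label_below(nd))
        node = next(counter)
        adj[node] = list(kids)
        for k in kids:
            adj[k].append(node)
        return node

    min_label_memo: dict[int, str] = {}

    def _min_label_below(node: int) -> str:
        if node in min_label_memo:
            return min_label_memo[node]
        if node in leaf:
            res = leaf[node]
        else:
            res = min(_min_label_below(ch) for ch in adj[node])
        min_label_memo[node] = res
        return res

    build(None)
    tree = UnrootedTree(adj, leaf)
    tree._suppress_degree_two()
    return tree
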