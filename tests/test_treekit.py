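import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from pqtree import (
    NewickError,
    TreeShapeError,
    majority_rule_extended_consensus,
    parse_newick,
    random_topology,
    restrict_tree,
    rf_distance_normalized,
)


def _rand_tree(n, seed, labels=None):
    return random_topology(n, np.random.default_rng(seed), labels=labels)


# ----------------------------------------------------------------- parsing


def test_parse_quartet_and_split():
    t = parse_newick("((A,B),(C,D));")
    assert t.leaf_labels == ("A", "B", "C", "D")
    assert t.nontrivial_splits() == {frozenset({"C", "D"})}


def test_parse_drops_branch_lengths_and_internal_labels():
    t1 = parse_newick("((A:0.1,B:0.2)x:0.05,(C,D)y);")
    t2 = parse_newick("((A,B),(C,D));")
    assert t1.nontrivial_splits() == t2.nontrivial_splits()


@pytest.mark.parametrize(
    "text,err",
    [
        ("((A,B),(C,D);", NewickError),  # unbalanced
        ("((A,B),(C,A));", NewickError),  # duplicate labels
        ("(A,B,C);", TreeShapeError),  # too few leaves for scoring
    ],
)
def test_parse_errors(text, err):
    with pytest.raises(err):
        parse_newick(text)


@pytest.mark.parametrize("n,seed", [(5, 0), (10, 1), (23, 2), (45, 3)])
def test_newick_round_trip_preserves_split_set(n, seed):
    t = _rand_tree(n, seed)
    back = parse_newick(t.to_newick())
    assert back.nontrivial_splits() == t.nontrivial_splits()
    # serialization is deterministic
    assert back.to_newick() == t.to_newick()


# ------------------------------------------------------------------- splits


@pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (10, 2), (45, 7)])
def test_binary_tree_has_n_minus_3_nontrivial_splits(n, seed):
    t = _rand_tree(n, seed)
    splits = t.nontrivial_splits()
    assert len(splits) == n - 3
    assert t.nontrivial_splits() == splits  # deterministic, set-equal


def test_induced_quartet_pairing_examples():
    t = parse_newick("((A,B),(C,D));")
    assert t.induced_quartet_split(["A", "B", "C", "D"]) == 0
    cat = parse_newick("(((A,B),C),D,E);")
    # on {A,C,D,E} the tree groups A with C against D, E
    assert cat.induced_quartet_split(["A", "C", "D", "E"]) == 0
    assert cat.induced_quartet_split(["A", "D", "C", "E"]) == 1


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_induced_quartet_agrees_with_restriction(seed):
    t = _rand_tree(8, seed)
    labels = t.leaf_labels
    for quartet in itertools.combinations(labels, 4):
        p = t.induced_quartet_split(quartet)
        r = restrict_tree(t, quartet)
        (split,) = r.nontrivial_splits()
        partner = next(iter(split - {quartet[0]})) if quartet[0] in split else None
        if partner is None:
            # quartet[0] sits on the complementary side
            other = set(quartet) - split
            partner = next(iter(other - {quartet[0]}))
        assert quartet.index(partner) == p + 1


# ----------------------------------------------------------------------- RF


def test_rf_identical_topologies_is_zero():
    a = _rand_tree(10, 5)
    b = parse_newick(a.to_newick())
    assert rf_distance_normalized(a, b) == 0.0


def test_rf_anchor_fractions():
    t10 = _rand_tree(10, 0)
    one_nni = t10.nni(t10.internal_edges_canonical()[0], 0)
    assert rf_distance_normalized(t10, one_nni) == pytest.approx(1 / 7)
    t45 = _rand_tree(45, 0)
    edges = t45.internal_edges_canonical()
    two_nni = t45.nni(edges[0], 0).nni(edges[-1], 1)
    assert rf_distance_normalized(t45, two_nni) == pytest.approx(2 / 42)


def test_rf_leaf_set_mismatch_raises():
    with pytest.raises(TreeShapeError):
        rf_distance_normalized(_rand_tree(6, 0), _rand_tree(7, 0))


@pytest.mark.parametrize("seed", range(6))
def test_rf_matches_dendropy_symmetric_difference(seed):
    n = 12
    a = _rand_tree(n, seed)
    b = _rand_tree(n, seed + 100, labels=a.leaf_labels)
    tns = dendropy.TaxonNamespace()
    da = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns)
    db = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns)
    da.encode_bipartitions()
    db.encode_bipartitions()
    expected = treecompare.symmetric_difference(da, db) / (2 * (n - 3))
    assert rf_distance_normalized(a, b) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(4))
def test_rf_is_a_metric_on_random_triples(seed):
    n = 9
    a = _rand_tree(n, seed)
    b = _rand_tree(n, seed + 50, labels=a.leaf_labels)
    c = _rand_tree(n, seed + 90, labels=a.leaf_labels)
    dab = rf_distance_normalized(a, b)
    dba = rf_distance_normalized(b, a)
    assert dab == dba >= 0
    assert (dab == 0) == (a.nontrivial_splits() == b.nontrivial_splits())
    assert rf_distance_normalized(a, c) <= dab + rf_distance_normalized(b, c) + 1e-12


# -------------------------------------------------------------- restriction


def test_restrict_to_full_leaf_set_is_identity():
    t = _rand_tree(8, 3)
    r = restrict_tree(t, t.leaf_labels)
    assert r.nontrivial_splits() == t.nontrivial_splits()


def test_restriction_splits_come_from_parent_tree():
    t = _rand_tree(10, 4)
    subset = list(t.leaf_labels[:6])
    r = restrict_tree(t, subset)
    assert set(r.leaf_labels) == set(subset)
    assert r.is_binary
    parent = {frozenset(s & set(subset)) for s in _both_sides(t)}
    for side in r.nontrivial_splits():
        assert side in parent or frozenset(set(subset) - side) in parent


def _both_sides(tree):
    labels = set(tree.leaf_labels)
    for s in tree.nontrivial_splits():
        yield set(s)
        yield labels - s


def test_restrict_errors():
    t = _rand_tree(8, 3)
    with pytest.raises(TreeShapeError):
        restrict_tree(t, t.leaf_labels[:3])
    with pytest.raises(TreeShapeError):
        restrict_tree(t, list(t.leaf_labels[:3]) + ["nope"])


# --------------------------------------------------------------- consensus


def test_consensus_of_identical_trees_is_that_tree():
    t = _rand_tree(9, 8)
    cons = majority_rule_extended_consensus([t.copy() for _ in range(5)])
    assert cons.nontrivial_splits() == t.nontrivial_splits()


def test_consensus_keeps_strict_majority_split():
    a = parse_newick("((a,b),(c,(d,e)));")
    b = parse_newick("((a,b),(d,(c,e)));")
    c = parse_newick("((a,c),(b,(d,e)));")
    cons = majority_rule_extended_consensus([a, b, c])
    assert frozenset({"d", "e"}) in cons.nontrivial_splits()  # 2 of 3 trees
    assert cons.is_binary


def test_consensus_requires_identical_leaf_sets():
    with pytest.raises(TreeShapeError):
        majority_rule_extended_consensus([_rand_tree(6, 0), _rand_tree(7, 0)])


# --------------------------------------------------------------- neighbors


@pytest.mark.parametrize("n", [4, 6, 9])
def test_nni_neighborhood_size_and_distance(n):
    t = _rand_tree(n, 21)
    nbrs = t.nni_neighbors()
    assert len(nbrs) == 2 * (n - 3)
    keys = {frozenset(x.nontrivial_splits()) for x in nbrs}
    assert len(keys) == len(nbrs)  # all distinct
    for nb in nbrs:
        assert rf_distance_normalized(t, nb) == pytest.approx(1 / (n - 3))


def test_spr_neighborhood_contains_nni_and_is_valid():
    t = _rand_tree(7, 22)
    spr = t.spr_neighbors()
    spr_keys = {frozenset(x.nontrivial_splits()) for x in spr}
    for nb in t.nni_neighbors():
        assert frozenset(nb.nontrivial_splits()) in spr_keys
    for cand in spr:
        assert cand.is_binary
        assert cand.leaf_labels == t.leaf_labels


def test_spr_neighborhood_of_quartet_equals_nni():
    t = parse_newick("((a,b),(c,d));")
    assert len(t.spr_neighbors()) == len(t.nni_neighbors()) == 2
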