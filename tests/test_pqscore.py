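import itertools
import warnings

import numpy as np
import pytest

from pqtree import (
    Alignment,
    ScoreConfig,
    blosum62,
    build_quartet_table,
    cross_max,
    identity_matrix,
    parse_newick,
    quartet_column_score,
    tree_score,
    tree_score_direct,
)
from pqtree.pqscore import all_quartets, quartet_ranks
from conftest import random_case

IDENT = identity_matrix()


def _eq1_reference(letters, split, matrix):
    """Literal base formula: max(s1 - X, 0) + max(s2 - X, 0)."""
    sides = {0: ((0, 1), (2, 3)), 1: ((0, 2), (1, 3)), 2: ((0, 3), (1, 2))}[split]
    (i, j), (k, l) = sides
    s = matrix.score
    x = max(
        s(letters[i], letters[k]),
        s(letters[i], letters[l]),
        s(letters[j], letters[k]),
        s(letters[j], letters[l]),
    )
    return max(s(letters[i], letters[j]) - x, 0) + max(s(letters[k], letters[l]) - x, 0)


def _identity_case_analysis(letters, split):
    """The printed identity-matrix case table: 0 / 1 / 2 by letter pattern."""
    sides = {0: ((0, 1), (2, 3)), 1: ((0, 2), (1, 3)), 2: ((0, 3), (1, 2))}[split]
    (i, j), (k, l) = sides
    side1 = {letters[i], letters[j]}
    side2 = {letters[k], letters[l]}
    if side1 & side2:
        return 0
    return (len(side1) == 1) + (len(side2) == 1)


def test_identity_column_score_matches_case_analysis_exhaustively():
    cfg = ScoreConfig(IDENT, alpha=1)
    for letters in itertools.product("ACGT", repeat=4):
        for split in range(3):
            got = quartet_column_score(letters, split, cfg)
            assert got == _identity_case_analysis(letters, split)
            assert got == _eq1_reference(letters, split, IDENT)


def test_generalized_score_reduces_to_base_form_at_alpha_one():
    cfg = ScoreConfig(IDENT, alpha=1.0)
    for letters in itertools.product("ACGT", repeat=4):
        for split in range(3):
            assert quartet_column_score(letters, split, cfg) == _eq1_reference(
                letters, split, IDENT
            )


def test_alpha_scales_only_doubly_supported_columns():
    cfg3 = ScoreConfig(IDENT, alpha=3)
    cfg1 = ScoreConfig(IDENT, alpha=1)
    assert quartet_column_score("AACC", 0, cfg3) == 6  # 3 * (1 + 1 - 0)
    assert quartet_column_score("AACC", 0, cfg1) == 2
    assert quartet_column_score("AACG", 0, cfg3) == 1  # single support unscaled
    assert quartet_column_score("AACA", 0, cfg3) == 0


def test_all_identical_letters_score_zero_under_any_matrix(blosum_cfg):
    for letter in ("A", "W"):
        for split in range(3):
            assert quartet_column_score((letter,) * 4, split, blosum_cfg) == 0


def test_cross_max_is_max_of_the_four_cross_pairs():
    b62 = blosum62()
    expected = max(
        b62.score("I", "D"), b62.score("I", "E"), b62.score("L", "D"), b62.score("L", "E")
    )
    assert cross_max(("I", "L", "D", "E"), 0, b62) == expected == -3
    assert cross_max(("A", "A", "C", "G"), 0, IDENT) == 0
    assert cross_max(("A", "A", "C", "A"), 0, IDENT) == 1


def test_score_invariant_under_side_and_member_swaps(blosum_cfg):
    rng = np.random.default_rng(3)
    letters_pool = "ARNDCQEGH"
    for _ in range(50):
        a, b, c, d = rng.choice(list(letters_pool), size=4)
        base = quartet_column_score((a, b, c, d), 0, blosum_cfg)
        assert quartet_column_score((b, a, c, d), 0, blosum_cfg) == base
        assert quartet_column_score((a, b, d, c), 0, blosum_cfg) == base
        assert quartet_column_score((c, d, a, b), 0, blosum_cfg) == base


# ------------------------------------------------------------------ tables


def test_toy_table_sums_and_maximum(toy_alignment, identity_cfg):
    table = build_quartet_table(toy_alignment, identity_cfg)
    assert table.n_quartets == 1
    assert list(table.scores[0]) == [4, 0, 0]  # 2 columns x double support
    assert table.q_max_total == 4


def test_gap_column_is_skipped_when_gaps_ignored(identity_cfg):
    aln = Alignment(("s1", "s2", "s3", "s4"), ("AA", "AA", "CC", "C-"))
    table = build_quartet_table(aln, identity_cfg)
    assert list(table.scores[0]) == [2, 0, 0]


def test_fully_conserved_alignment_scores_zero(identity_cfg):
    aln = Alignment(("s1", "s2", "s3", "s4"), ("AAA",) * 4)
    table = build_quartet_table(aln, identity_cfg)
    assert table.scores.sum() == 0 and table.q_max_total == 0
    t = parse_newick("((s1,s2),(s3,s4));")
    res = tree_score(table, t)
    assert res.q == 0 and res.s == 0.0


def test_all_gap_quartets_warn_and_zero(identity_cfg):
    aln = Alignment(("s1", "s2", "s3", "s4"), ("A-", "-A", "A-", "-A"))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = build_quartet_table(aln, identity_cfg)
    assert any("admitted" in str(w.message) for w in caught)
    assert table.q_max_total == 0


def test_quartet_rank_formula_matches_lexicographic_enumeration():
    for n in (4, 5, 8, 12):
        quads = all_quartets(n)
        ranks = quartet_ranks(n, quads)
        assert list(ranks) == list(range(len(quads)))


@pytest.mark.parametrize("gap_mode", ["ignore", "gap_as_letter", "at_most_one_gap"])
def test_table_score_equals_brute_force_with_gaps(gap_mode):
    cfg = ScoreConfig(IDENT, gap_mode=gap_mode)
    rng = np.random.default_rng(17)
    for seed in (1, 2):
        true_tree, aln = random_case(6, 25, 0.3, seed=seed)
        # punch gaps into ~10% of cells
        rows = []
        for row in aln.rows:
            chars = list(row)
            for c in range(len(chars)):
                if rng.random() < 0.1:
                    chars[c] = "-"
            rows.append("".join(chars))
        aln = Alignment(aln.ids, tuple(rows))
        table = build_quartet_table(aln, cfg)
        tree = parse_newick(true_tree.to_newick())
        a = tree_score(table, tree)
        b = tree_score_direct(aln, tree, cfg)
        assert (a.q, a.q_max) == (b.q, b.q_max)


def test_blosum_table_matches_brute_force():
    cfg = ScoreConfig(blosum62())
    true_tree, aln = random_case(5, 20, 0.2, seed=9, alphabet="ARNDCQEGH")
    table = build_quartet_table(aln, cfg)
    a = tree_score(table, true_tree)
    b = tree_score_direct(aln, true_tree, cfg)
    assert (a.q, a.q_max) == (b.q, b.q_max)


def test_score_is_additive_over_columns(identity_cfg):
    _, aln = random_case(5, 30, 0.3, seed=4)
    left = aln.take_columns(range(15))
    right = aln.take_columns(range(15, 30))
    t_left = build_quartet_table(left, identity_cfg)
    t_right = build_quartet_table(right, identity_cfg)
    t_full = build_quartet_table(aln, identity_cfg)
    assert np.array_equal(t_left.scores + t_right.scores, t_full.scores)
    assert t_left.q_max_total + t_right.q_max_total == t_full.q_max_total


def test_normalized_score_bounds_and_table_invariants(identity_cfg):
    for seed in (1, 5, 9):
        true_tree, aln = random_case(7, 60, 0.25, seed=seed)
        table = build_quartet_table(aln, identity_cfg)
        assert (table.scores >= 0).all()
        # per-column maxima dominate maxima of column sums
        assert table.q_max_total >= table.scores.max(axis=1).sum()
        for probe_seed in (11, 12):
            probe = np.random.default_rng(probe_seed)
            from pqtree import random_topology

            t = random_topology(7, probe, labels=true_tree.leaf_labels)
            res = tree_score(table, t)
            assert 0 <= res.q <= res.q_max
            assert 0.0 <= res.s <= 1.0


def test_tree_score_rejects_leaf_set_mismatch(toy_alignment, identity_cfg):
    from pqtree import TreeShapeError

    table = build_quartet_table(toy_alignment, identity_cfg)
    with pytest.raises(TreeShapeError):
        tree_score(table, parse_newick("((a,b),(c,d));"))


def test_perfect_tree_reaches_normalized_score_one(toy_alignment, identity_cfg):
    table = build_quartet_table(toy_alignment, identity_cfg)
    assert tree_score(table, parse_newick("((s1,s2),(s3,s4));")).s == 1.0
    assert tree_score(table, parse_newick("((s1,s3),(s2,s4));")).s == 0.0
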