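# Methods

## The criterion

Given a multiple alignment of N ≥ 4 sequences and an unrooted binary
tree T leaf-labeled by the sequences, every four-element subset
{i, j, k, l} of sequences is split by T into two pairs, say
{i, j} | {k, l}.  Fix a symmetric scoring matrix S(a, b) (BLOSUM62 for
proteins; for nucleotides the identity matrix with 1 on the diagonal and
0 elsewhere).  Writing a_ic for the letter of sequence i in column c,
the support of column c for the quartet's split is

    Q_cq = max(S(a_ic, a_jc) − X_cq, 0) + max(S(a_kc, a_lc) − X_cq, 0),
    X_cq = max(S(a_ic,a_kc), S(a_ic,a_lc), S(a_jc,a_kc), S(a_jc,a_lc)).

X_cq is the best cross-split pair score — the baseline a side must beat
before it counts as evidence for the split.  Under the identity matrix
this reduces to a three-valued case table: 2 when both sides are
monomorphic for two different letters, 1 when exactly one side is
monomorphic and the remaining letters are all different from it and from
each other, 0 whenever any letter is shared across the split or all four
letters differ.

The tree score is Q = Σ_c Σ_q Q_cq over all columns and quartets.  A
generalized form rewards doubly supported columns: for a weight α > 0,
when both sides strictly exceed X_cq the contribution becomes
α·(S_side1 + S_side2 − 2·X_cq); at α = 1 it coincides with the base
form (we accept any positive real α, not only integers).

**Normalization.**  Per column and quartet, the best of the three
possible splits is Q^m_cq = max over the three pairings of Q_cq; the
alignment maximum Q^m = Σ_c Σ_q Q^m_cq depends only on the alignment.
The normalized score S = Q / Q^m lies in [0, 1] (S := 0 when Q^m = 0)
and is comparable across alignments of different sizes.  Note the
maximum is taken **per column**: a `QuartetTable` stores column-summed
scores per split, and the sum over quartets of the per-quartet best
column sum is a lower bound on Q^m, not Q^m itself (the distinction is
property-tested).

**Gaps.**  Three modes: `ignore` (default) admits a (column, quartet)
pair only if all four letters are residues; `gap_as_letter` treats the
gap as one more alphabet letter; `at_most_one_gap` admits pairs with at
most one gap.  The matrix gives no gap scores, so in the two non-default
modes the matrix is extended with an explicit gap row: gap–gap defaults
to the minimum diagonal entry and gap–residue to the minimum
off-diagonal entry, both overridable in `ScoreConfig`.  The alignment
maximum uses the same admission rule as the realized sums so that S
compares like with like (any other choice breaks S ≤ 1).  Letters a
matrix does not know (X/B/Z/U, N, …) are treated as gaps, with a
warning.

**Arithmetic.**  Scores are accumulated as exact 64-bit integers
whenever the matrix and α are integral (BLOSUM62, identity); otherwise
as floats, with a 1e−9 tolerance on every "score improved" comparison.

## The quartet table and incremental scoring

`build_quartet_table` accumulates, for each of the C(N,4) quartets and
each of its three splits, the sum of Q_cq over admitted columns —
Θ(N⁴·L) work, vectorized over columns in quartet chunks.  Once built,
any tree is scored without revisiting the alignment:

* **Full evaluation** computes unit-branch-length leaf distances by BFS
  and reads each quartet's induced pairing off the four-point condition
  (the induced pairing's within-side distance sum is strictly smallest —
  on a binary tree the margin is at least 2, so ties cannot occur).
* **Stepwise attachment** of leaf x evaluates a candidate branch using
  only the quartets containing x (the rest are constant across
  candidates).  The attachment point w subdividing an edge (p, q) has
  d(w, t) = min(d(p,t), d(q,t)) + ½ up to a constant; subdividing the
  edge perturbs the other leaf–leaf distances by at most 1, below the
  four-point margin, so pairings are still read off correctly.
* **NNI deltas** touch only quartets with one leaf in each of the four
  subtrees around the edited edge; incremental and full recomputation
  agree exactly (asserted in tests after every edit).
* **SPR candidates** are rescored by the full table evaluation; no
  incremental scheme is attempted for SPR.

A lexicographic quartet ranking (combinatorial number system) maps
sorted index quartets to table rows in O(1).

## Search

All strategies break ties in favor of the first candidate in
deterministic traversal order and return binary trees on exactly the
input leaf set.

* **Stepwise addition** places the first four sequences on the best of
  three topologies, then attaches each remaining sequence at the branch
  maximizing the gain among the 2m−3 branches of the current m-leaf
  tree.
* **Multiple stepwise addition** repeats with uniformly shuffled input
  orders and keeps the first-attained best.
* **NNI hill climbing** is first-improvement: scan the 2(n−3) NNIs in
  canonical edge order (edges sorted by their canonical split), take the
  first strict improvement, restart the scan; stop when no NNI improves.
* **NNI Monte Carlo** starts at temperature T_ini = 1000 with constant
  K = 12·10⁶; a strictly better tree is always accepted, a strictly
  worse one with probability P = exp((K/T)·ΔQ/Q_old), and equal scores
  are rejected.  T drops by T_ini/N (N = 1000) after every proposal,
  accepted or not, so the run makes exactly N proposals; the best tree
  among all visited is returned.  When Q_old = 0 the downhill
  probability is defined as 0.  Whether the original decrements per
  proposal or per sweep is unstated; per-proposal is our choice, as is
  restarting the canonical proposal order after each accepted move.
* **SPR hill climbing** is the same ascent over the full
  prune-and-regraft neighborhood (deduplicated by split set), which
  contains the NNI neighborhood.

`infer` builds the table once; the default pipeline is tenfold stepwise
addition followed by NNI hill climbing, and the Monte Carlo and SPR
refinements also start from the tenfold-stepwise best.  An exhaustive
enumerator over all (2n−5)!! topologies serves as the optimality oracle
for n ≤ 8.

## Trees, distances, consensus

Trees are adjacency maps with O(1) NNI edits; Newick reading is
delegated to dendropy (lengths and internal labels discarded, a
degree-2 root suppressed), writing is our own deterministic serializer
(topology only, rooted for output at the internal vertex adjacent to the
lexicographically smallest leaf, children ordered by smallest descendant
label).  Splits are stored canonically as the side not containing the
globally smallest label.

The normalized Robinson–Foulds distance is the size of the symmetric
difference of the two nontrivial split sets divided by their total
count — d/(n−3) when each binary tree holds d splits absent from the
other.  Polytomies are rejected; the normalization for non-binary trees
is never needed here.

The greedy ("majority rule extended") consensus accepts all splits in
more than half the input trees, then adds remaining splits in decreasing
frequency order when compatible (ties broken by lexicographically
smallest canonical split — the reference implementation leaves greedy
tie order unspecified, so determinism is imposed).  If the accepted
splits do not fully resolve the topology, remaining polytomies are
resolved deterministically by repeatedly joining the two children with
the smallest labels; with binary, mutually similar inputs (the intended
use) the candidate pool itself resolves the tree.

## Benchmark statistics

`pairwise_compare` counts alignments where one method's tree is strictly
closer to the reference than another's (ties dropped) and tests the two
counts with the **one-sided** exact sign test, P(X ≥ max(m, n)) under
Binomial(m+n, ½).  The sidedness convention is reverse-engineered from
the published benchmark p-values, which match the one-sided tail exactly
(13/0 → 1.2·10⁻⁴ = 0.5¹³; 17/2 → 3.6·10⁻⁴) and not the two-sided
doubling; it is symmetric in (m, n) by construction.  When every pair is
tied the comparison reports p = 1.

Quartile good/bad counts use the inclusive linear-interpolation quantile
(numpy's default) for the reference method's lower and upper quartiles
and strict inequalities for the counts, so distances taking few distinct
values yield counts below a quarter of the list.  Correlations are
Pearson.  Median alignment length is the lower median for even
cardinality, keeping the statistic an attainable integer length.

The long-branch-attraction diagnostic asks whether a reconstruction
contains the split {x, y} | rest for a designated pair of lone,
fast-evolving taxa; the paired m/n counts over two restricted-alignment
tests feed the same sign test.  Selecting *which* taxa are the fast
pair requires ML distance matrices and is out of scope — restricted
alignments are taken as given.

## Synthetic data

The generator is a simple stand-in for full simulators, chosen because
its job is test signal with a known truth, not realism (published
simulation protocols are documented but deliberately not reimplemented;
simulated data are known to behave unlike natural alignments).  A
uniformly random binary unrooted topology is grown by attaching each
leaf to a uniformly chosen edge; sequences evolve from a uniform root by
independent per-site point substitutions (each mutated site jumps to a
uniformly chosen different letter) with a per-branch probability, either
fixed or drawn per branch from a range.  Optional gaps are whole columns
gapped in a random row subset — enough to exercise the three gap modes.
Duplicate rows are re-drawn up to 20 times, then reported.  The rRNA
subsampling protocol is reproduced as stated: 15 random rows and a
random 300–800-column subset, order preserved, with the reference being
the species tree restricted to the chosen rows.

Default study conditions (frozen once): nucleotide alphabet with the
identity matrix, L = 500, per-branch substitution probability 0.05
(low noise), no gaps.  What passing recovery tests show is that the
criterion and search recover the generating topology under clean point
substitution; they say nothing about rate heterogeneity, indel
processes, alignment error or compositional bias, none of which the
generator emulates.

## Cost model and problem sizes

Table construction is Θ(N⁴·L) in sequences and informative columns;
with the table in memory (Θ(N⁴)), the default pipeline's remaining work
scales near N⁵.  The scaling tests assert a log-log slope on an
operation count (`pqscore.OP_COUNTER`: one unit per (column, quartet)
pair during table build, one per quartet touched per lookup) rather than
wall-clock, which at small N is dominated by interpreter overhead; the
measured slope across N ∈ {10, 15, 20} at L = 200 is ≈ 5.1, matching
the fifth-power rule.

Test problem sizes are chosen to keep the suite fast while leaving the
assertions sharp: exhaustive-optimality replicates use 6–7 taxa (105 /
945 topologies), brute-force equivalence uses n ≤ 8 with short
alignments, and recovery experiments use 10 taxa at L ∈ {100, 300, 500}.

## Known limitations

* Branch lengths are neither estimated nor written; output is topology
  only (external tools estimate lengths if needed).
* Consensus on wildly discordant inputs may need the deterministic
  polytomy-resolution fallback, whose extra splits come from no input
  tree.
* The full published-benchmark reproduction (mean scores/distances on
  the curated protein sets, median lengths, LBA counts) requires the
  multi-gigabyte supplementary archives; the pipeline is implemented
  and tested end-to-end on synthetic layouts, and the corresponding
  full-scale test fails fast with instructions when the archives are
  absent.
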