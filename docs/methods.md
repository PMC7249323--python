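# Methods

## Setting

A population of `n` cells carries two partitions: a reference `R` with
`J` cell types (treated as ground truth) and a clustering `C` with `I`
clusters, where `I` need not equal `J` and cluster labels are
arbitrary.  All comparisons start from the J×I contingency table
`n_ji` of joint counts; cells are matched by identifier, never by row
position, because label files from different tools order cells
differently.

## Weighted Rand index

Each of the C(n,2) cell pairs receives a score depending on the pair's
reference types *(i, j)* and on whether `C` co-clusters it:
`W1[i,j]` if co-clustered, `W0[i,j]` if separated.  The weighted
agreement score `S*(C,R)` sums these, and
`wRI = S*(C,R) / S*(R,R)`, where `S*(R,R)` scores the reference
against itself.  Both matrices are symmetric with entries in [0, 1];
the canonical form fixes `diag(W1) = 1` and off-diagonal `W0 = 1`, so
a perfect clustering scores 1 and `S*(R,R) = C(n,2)`.  Identity
weights (`W1 = I`, `W0 = 1 − I`) recover the classical RI exactly; the
weighted predictive values wPPV/wNPV (mean pair score among
co-clustered / separated pairs) likewise reduce to `N11/N+1` and
`N00/N+0`.

The implementation aggregates pairs through the contingency table in
O(I·J²): within a cluster, same-type pairs contribute
`C(n_ji, 2)·W1[j,j]` and cross-type pairs `n_ji·n_j'i·W1[j,j']`; all
remaining pairs of each type combination take the corresponding `W0`
entry.  A literal O(n²) enumeration over all pairs
(`pairwise_oracle`, capped at n = 5000) is kept as an independent
check and is exposed on the CLI as `oracle`.

Weight-matrix handling: matrices are filled from the upper triangle
(lower entries are ignored; a populated lower triangle that disagrees
with the upper beyond 1e-8 is an error).  Canonical form is enforced
by default with `canonical=False` as the escape hatch, since the
definitions are valid for arbitrary weights but the interpretation of
wRI as "agreement relative to a perfect clustering" assumes the
canonical form.  No chance-corrected variant of wRI is provided — the
permutation-null correction of ARI has no established analogue for
weighted pair scores, and guessing one here would change the metric's
meaning.

## Structured entropy and weighted NMI

The reference tree is a rooted ultrametric dendrogram over the `J`
types with strictly positive internal-node heights.  Cutting below the
(j−1)-th highest node yields nested partitions `R_1` (one group) …
`R_J` (the leaf typing); the step weights `d_j` are the internal
heights sorted descending and divided by the maximum, so `d_1 = 1`
and `d` is non-increasing.  The structured entropy is

    H*(R) = Σ_{j=1}^{J−1} d_j · [H(R_{j+1}) − H(R_j)],

using the nested-partition identity
`H(R_{j+1} | R_j) = H(R_{j+1}) − H(R_j)`.  Conditioning every step on
`C` uses the joint-entropy identity `H(R_j | C) = H(R_j, C) − H(C)`;
the per-cluster weighted-average formulation is implemented separately
and used as the test oracle for this identity.  Then
`wMI = H*(R) − H*(R|C)` and

    wNMI = wMI / H*(R) · H(R) / ((H(R) + H(C)) / 2).

The first factor is the share of structured entropy explained (an
R²-like quantity); the second penalizes clusterings whose complexity
is out of balance with the reference, so trivially over-split
clusterings do not win.

Numerical and structural choices:

* **Log base.**  Natural logarithm throughout.  NMI and wNMI are
  provably base-invariant (every entropy rescales by the same
  constant); this is asserted numerically by computing with `base=2`.
* **Multifurcations and exact height ties.**  A node with `m` children
  is represented as `m−1` consecutive binary merges at the same
  height, keeping the `R_j` sequence strictly nested with unit steps.
  Among distinct nodes with exactly tied heights the cut order follows
  the merge-row order (parents before children within a tie, so cuts
  stay nested); the entropy sums are invariant to this choice because
  tied steps carry equal `d` — asserted by test.
* **wNMI > 1.**  When a coarse clustering merges types separated only
  at a very small height, the complexity-balance factor can exceed the
  structured-entropy share's shortfall and wNMI exceeds 1 (the 8-cell
  fixture gives 12/11).  The value is reported as computed, not
  clipped: clipping would hide exactly the behaviour the metric is
  designed to expose.
* **Degenerate inputs.**  A reference with a single observed type has
  `H*(R) = 0` and wNMI is refused (`DegenerateMetricError`, CLI exit
  3).  ARI of two trivial partitions returns 1 by documented
  convention.  A clustering with no co-clustered or no separated pairs
  has an undefined wPPV or wNPV side, reported as NaN with a warning
  rather than silently as 0.

Trees are read from Newick with branch lengths; node heights are
reconstructed as maximum root-to-leaf depth minus root-to-node depth,
with an ultrametricity check at relative tolerance 1e-6
(overridable).  A merge-table CSV (`step,height,members`) mirroring
agglomerative-clustering output is accepted as an alternative.

## Estimating weights and tree from expression

When no external hierarchy is available, both weight matrices and the
tree are derived from the labelled expression matrix itself:

1. per-type mean profiles of `log(x+1)` expression (the pseudocount
   accommodates zero-heavy scRNA-seq counts; the log base is
   irrelevant because gene ranking and Pearson correlation are
   affine-invariant, asserted by test);
2. the top `k = 1000` genes by across-type variance of the mean
   profiles (stable ties by gene order; `k` capped at the gene count
   with a warning);
3. `W1` off-diagonal = Pearson correlation of two types' mean profiles
   over the selected genes, clamped below at 0 to respect the [0, 1]
   range; diagonal fixed at 1;
4. `W0` diagonal = 1 − mean pairwise Pearson correlation among the
   type's cells (clamped into [0, 1]); off-diagonal fixed at 1.  A
   single-cell type gets diagonal 0 — no heterogeneity is measurable,
   so splitting it carries the full penalty — with a warning.  The
   alternative heterogeneity measure (mean `1 − r` between each cell
   and the type mean) is available as `method="to_mean"`;
5. the tree by complete-linkage agglomerative clustering of the type
   mean profiles under Euclidean distance (both configurable — no
   single convention is canonical for type-level clustering), heights
   standardized by the maximum.

The same gene set serves all three estimates; the two natural reading
of "most variable genes" (variance of type means vs between-type
variation) coincide under this criterion.  Batch correction,
normalization and imputation are deliberately out of scope: the API
expects a matrix already comparable across cells.

`weights_from_tree` additionally derives canonical weights from a tree
alone (`W1[i,j] = 1 −` standardized MRCA height; `W0` diagonal chosen
by the user, default 0), for settings where the hierarchy is known but
expression is not.

## Synthetic populations

The generator draws a root mean log-profile with i.i.d. `N(1, 1)`
genes and lets it drift along the tree: each branch adds independent
`N(0, drift²·branch_length)` per gene (Brownian motion in log space),
so expected expression distance between types tracks patristic
distance and recovery of the hierarchy is well-posed.  Cells are drawn
per type under a lognormal-rounded model
(`round(exp(profile + N(0, σ)) − 1)`, default σ = 0.5) or a negative
binomial with user dispersion.  Defaults — 100 cells per type, 1000
genes, drift 1.0 per unit branch — mirror a modestly sized labelled
study.  One seed drives a hierarchical `SeedSequence` split (profile /
drift / noise), so each stage is independently reproducible and a
fixed seed yields bitwise-identical output.

What the simulator does **not** model: library-size variation,
dropout, batch effects, gene-gene correlation within a type.  Passing
tests therefore demonstrate correctness of the estimators under clean
hierarchical signal, not robustness to every artefact of real
scRNA-seq data.

Controlled clustering errors (`perturb_clustering`) move a chosen
number of cells: into the sibling type's cluster, into the most
distant type's cluster, out into a new cluster, or to random other
clusters (seeded).

## Validation study sizes

The fast weighted-Rand path is checked against the pair-enumeration
oracle on 100 random comparisons (n ≤ 200, J ≤ 8, I ≤ 10, random
canonical weights) at 1e-12; the entropy chain rule on 100 random
trees and labelings at 1e-12; ARI/NMI against scikit-learn on 100
random comparisons at 1e-12.  Estimation recovery uses 100 simulated
populations of five types on a caterpillar tree with split heights
0.25/0.5/0.75/1.0 at the default noise level, asserting ≥ 95% exact
topology recovery and median |Spearman ρ| > 0.9 between estimated `W1`
off-diagonals and true patristic distances.  The caterpillar topology
is used because its distance spectrum is minimally degenerate: on
balanced topologies many leaf pairs share the root as MRCA, and the
resulting rank ties cap the attainable |ρ| well below 1 (at ≈ 0.88 for
a balanced five-type tree) no matter how good the estimate is.

## Known limitations

* wRI/wNMI inherit the quality of the supplied hierarchy and weights;
  the estimation route reuses the data being clustered, which is
  convenient but not independent — for method comparisons, weights
  fixed before evaluation are preferable.
* Within-type heterogeneity enters `W0` only through mean pairwise
  correlation; structured substates within a type are not modelled.
* The Newick reader requires branch lengths and near-ultrametric
  depths; trees with topology but no lengths must be given heights by
  the user (e.g. unit-depth per level) before use.
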