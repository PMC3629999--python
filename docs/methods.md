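# Methods

## Model and scoring

The data are a bipartite association network between *n* miRNAs and *m*
disease phenotypes (binary adjacency `a`, rows = miRNAs) plus two square
similarity matrices: miRNA functional similarity `M` and phenotype
similarity `P`, both nonnegative with entries on a [0, 1] scale. Verified
associations are 1s in `a`; every 0 is an *unlabelled* pair, not a negative
— all methods are ranking methods and none consumes negative examples.

**MBSI** scores pair (i, j) as the similarity-weighted mean of the other
miRNAs' association indicators for phenotype j, with the self term l = i
excluded; **PBSI** is the mirror construction over phenotypes. Both scores
are convex combinations of binary values, hence in [0, 1], and invariant to
any positive rescaling of the similarity matrix (numerator and denominator
scale together). A miRNA (phenotype) with zero similarity to all others has
an empty evidence base; its scores are defined as 0 rather than NaN.

**NetCBI** measures network consistency. The similarity matrix is first
column-normalized, `M̄_:,i = M_:,i / Σ M_:,i` (zero-sum columns stay zero —
an entity with no similarity information should not be imputed a uniform
profile, and leaving the column zero keeps `I − αM̄` well conditioned). The
relevance of all miRNAs to a query indicator `m` is the minimiser of a
graph-smoothness penalty plus an α-weighted fidelity term, with closed form

    m̃ = (1 − α)(I − αM̄)⁻¹ m ,   α ∈ (0, 1)

and analogously `p̃` with parameter β on the phenotype side. For
column-stochastic `M̄` this equals the geometric series
`(1 − α) Σ_k α^k M̄^k m`, which the tests use as an independent oracle; it
also conserves the query mass (`1ᵀm̃ = 1ᵀm`). The score of candidate
phenotype j for a query miRNA is `corr(a·p̃_j, m̃)` — Pearson correlation
between the evidence profile that j projects onto the miRNA axis and the
query's relevance profile. If either vector has zero variance (e.g. an
all-zero adjacency) the correlation is defined as 0, treating "no signal" as
neutral rather than letting NaN poison the ranking.

The diagonal of each similarity matrix is used exactly as supplied:
MBSI/PBSI exclude the self term explicitly, so the diagonal only enters the
NetCBI propagation, where a self-similarity convention is part of the input
data, not of the method. Asymmetric input similarity is warned about but
accepted — column normalization breaks symmetry regardless.

## Numerical choices

- Propagation solves use one LU factorization of `I − αS̄` shared across all
  right-hand sides (`relevance_matrix`); a residual contract of
  `1e-8 · ‖q‖` is enforced on single solves. No explicit inverses.
- Removing a query miRNA's adjacency row changes exactly one row of
  `a·P̃`, so LOOCV and the nested inner loops update that product in place
  instead of recomputing it; the tests verify equivalence with from-scratch
  runs.
- Ranking ties (equal scores) break lexicographically on
  (miRNA id, phenotype id); grid ties break toward the smallest (α, β).
  Both make outputs byte-reproducible across platforms.

## Evaluation protocol

Leave-one-out cross-validation removes, per query miRNA, the *entire*
adjacency row (all its associations, not one edge), re-scores all phenotypes
on the reduced network, and treats the removed phenotypes as positives. For
PBSI the query is a phenotype and its column is removed. Each distinct
candidate score is a threshold; TPF/FPF at every threshold give the ROC
curve, anchored at (0,0) and (1,1) and integrated by the trapezoidal rule.
This is provably equal to the pairwise-concordance statistic
`P(s_pos > s_neg) + ½ P(s_pos = s_neg)`; both routes are implemented and
must agree to 1e-12 (also cross-checked against scikit-learn in the tests).
The reported figure is the unweighted mean of per-query AUCs — one ROC per
query, not per association — matching the protocol in which all of a query's
candidate scores become available in one round. Queries with no associations
are skipped (nothing to hold out); queries associated with *every* candidate
have an undefined ROC and are excluded from the average with a logged note.

Two structural identities double as regression tests: MBSI's l ≠ i sum never
reads row i, and PBSI's l ≠ j sum never reads column j, so their held-out
scores equal the full-data scores; the removal is still performed for
protocol uniformity.

**Parameter tuning.** The default grid is {0.1, …, 0.9} step 0.1 on both α
and β (configurable). Plain grid search maximises the LOOCV mean AUC.
Nested LOOCV gives the unbiased estimate: each miRNA in turn is the
validation case; an inner LOOCV over the remaining miRNAs selects (α, β)
for that fold; the validation miRNA's AUC under the selected parameters is
recorded and averaged. The per-fold selections are summarised as
mean ± sd (an ambiguity exists in how such a spread can be summarised; this
package reports the mean and standard deviation of the per-fold choices).
The `selected` field of a nested result is the argmax of the fold-averaged
inner AUCs, keeping the invariant that `selected` maximises the recorded
grid AUCs.

## Synthetic data generator

The generator emulates the statistical assumption the methods rely on, and
nothing more. miRNAs and phenotypes are partitioned into `n_blocks` paired
communities; pairwise similarity is drawn from a normal around `within_sim`
(same block) or `between_sim` (different blocks) with sd `sim_noise`,
symmetrized, clipped to [0, 1], diagonal set to 1; associations are
independent Bernoulli edges with probability `edge_prob_matched` inside
paired blocks and `edge_prob_unmatched` otherwise. Defaults — 60 miRNAs,
30 phenotypes, 3 blocks, 0.7/0.1 similarity contrast with sd 0.05,
0.3/0.02 edge contrast — give a network of benchmark-like sparsity
(~3.6 associations per miRNA) with clear but noisy signal. Clipped-normal
jitter was chosen over beta noise for simplicity. All draws come from one
`numpy` generator seeded by `spec.seed`; identical specs give byte-identical
outputs.

The matched null is a degree-preserving checkerboard shuffle: repeatedly
pick two edges (i₁,j₁), (i₂,j₂) with the cross pairs absent and swap to
(i₁,j₂), (i₂,j₁). Both degree sequences are invariant by construction; the
attempt budget defaults to 10× the edge count, a standard mixing heuristic.

What the generator does **not** emulate: miRNA sequence families, the
text-mining noise structure of real phenotype similarity, hub diseases with
heavy-tailed degree distributions, or correlated (non-independent) edge
placement. Passing the synthetic-recovery tests therefore shows that the
implementation recovers planted similarity-association coupling and is
correctly calibrated at null; it does not by itself certify performance on
curated biological data, which the separate benchmark-reproduction test
covers when the published files are supplied.

In the synthetic-recovery checks, NetCBI is reported at its
grid-search-selected parameters — the same protocol used for the benchmark
figure, where the best LOOCV result over the grid is the quantity reported —
while the null and noise-channel runs use fixed α = β = 0.1, since parameter
choice is immaterial at chance level.

## Problem sizes

Evaluation and acceptance runs use the default 60 × 30 generator size with
five seeds, and a 5-point-per-axis grid for the nested procedure; unit tests
use 3–10-entity instances where oracles can be enumerated exhaustively.
These sizes give stable AUC means (sd across seeds ≈ 0.03) while keeping a
full run in the tens of seconds.

## Known limitations

- The phenotype-side channel is weaker by construction whenever phenotype
  similarity is noisy; PBSI inherits that directly.
- NetCBI scores are correlations over *n*-vectors; for very small n the
  correlation is high-variance and rankings are unstable.
- The CLI's unknown-entity filter matches identifiers exactly and
  case-sensitively; inputs from different resources need pre-cleaning.
- An edge list whose first line references an unknown miRNA *and* an unknown
  phenotype is indistinguishable from a header and treated as one.
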