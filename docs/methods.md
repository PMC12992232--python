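# Methods

## Evaluation object

The package evaluates a three-level indicator tree: one goal node, a layer
of criteria ("second-level indicators"), and leaf ("third-level")
indicators rated by an expert panel on an ordered grade scale, by default
the five-point importance Likert scale with values 1–5 (columns are always
stored lowest grade first). Weights attach to nodes and are interpreted
within sibling groups: any group weight vector is renormalized to sum to 1
before use, so globally scaled published weight tables and locally
normalized vectors are interchangeable.

The bundled case study — collaborative food-safety governance in Jilin
Province — carries 4 criteria (government regulatory capacity, corporate
responsibility implementation, third-party/testing quality, public
participation) and 18 leaves, a published weight table, the
regulatory-capacity block of the membership matrix, the four dimension
synthesis scores, and a 33-expert roster. All bundled values are stored
verbatim at their published precision; membership rows therefore sum to 1
only to ~1e-6 and are renormalized where exact distributions are needed.

## Weighting

**Entropy weight method.** X (items × indicators) is min–max normalized
per column; cost-oriented indicators use the mirrored form. Column
proportions p_ij give entropies E_j = −(ln n)⁻¹ Σ p_ij ln p_ij with the
0·ln0 := 0 convention, and weights W_j = (1 − E_j)/(k − ΣE). Numerical
choices:

* A constant raw column is normalized to all-0.5 and assigned E_j := 1
  exactly (hence weight 0), with a warning — an indicator with no
  variation carries no information, and the convention avoids 0/0.
* If *every* column has entropy 1 the weights are undefined and the
  computation raises rather than returning NaNs.

**AHP.** Judgment matrices are validated as positive reciprocal matrices
with entries in [1/9, 9]. Weights come from the principal eigenvector via
power iteration on the raw matrix (tolerance 1e-10, max 10 000
iterations); the row-geometric-mean approximation is available behind
`method="geometric"`. λmax is estimated as mean((A·w)/w), CI = (λmax −
n)/(n − 1), CR = CI/RI with the standard Saaty random indices, and CR := 0
for n ≤ 2 (2×2 reciprocal matrices are always consistent; RI = 0 would
make the ratio undefined).

**Likert → pairwise map.** Published group studies often form judgment
matrices from mean Likert ratings without stating the map. The package's
convention: d = round(mean_i − mean_j) clipped to [−4, 4], mapped
|d| = 0,1,2,3,4 → intensity 1,3,5,7,9, reciprocal for negative d. It is
monotone, reciprocal by construction, and spans the full Saaty range;
users needing a different map can construct `PairwiseMatrix` directly.

**Combination.** `combine_weights(w_a, w_b, alpha)` is the renormalized
convex combination — the package takes no position on whether subjective
(AHP) or objective (entropy) weights should dominate; the bundled weight
table is treated as a fixture, not as derivable from either route alone.

## Fuzzy comprehensive evaluation

Membership rows are response frequencies over the non-missing ratings of
each leaf; missing cells are permitted per cell, which reconciles a
33-expert roster with indicator blocks answered by only 17 respondents
without assuming who answered what. Synthesis is the weighted-average
(·, +) operator A = W·R — ordinary matrix algebra, which is what the
P = W·R·V formulation denotes and what reproduces the case study's
arithmetic. Max–min composition is available behind a flag for comparison;
its output is renormalized to a distribution but it is never the default.
Defuzzification is the expectation P = A·V on the scale values.

Grade assignment is two-fold: (a) the raw score's bracketing scale labels
(e.g. 3.63 lies between "average" and "important"); (b) a performance band
on the normalized axis (score − 1)/4 ∈ [0, 1], partitioned poor [0, 0.2),
average [0.2, 0.4), medium [0.4, 0.6), good [0.6, 0.8), excellent
[0.8, 1.0] — bands are lower-inclusive, top band closed at 1. The
normalization reconciles band boundaries stated on a 0–1 axis with scores
living on 1–5.

The fixed-score aggregation mode (`aggregate_fixed_scores`) computes the
weighted sum of given per-criterion scalar scores. It exists because the
case study publishes coarse dimension scores (4, 3, 3.5, 3.5) whose origin
is not derivable from the printed partial membership matrix (direct
aggregation of the regulatory-capacity block gives ≈ 3.572, not 4); both
modes are provided and neither is forced to reproduce the other. The
published overall total of 3.6363 would require the full 18-row membership
matrix, which is not printed; the dimension-table composite (3.6339 →
3.63) is the reproducible headline.

## Robustness suite

**Sensitivity.** A target weight is multiplied by (1 + δ) and the whole
vector renormalized before recomputation. Renormalization is the only
reading consistent with the case study's own finding: without it, ±10 % on
a 0.385 weight moves the composite by ≈ 0.15, not ≤ 0.03. The sweep
enumerates {+δ, −δ} × targets and reports the maximum absolute change.

**Bootstrap stability.** Experts are resampled without replacement at a
fixed fraction (default 0.8 — the published procedure states 10 groups but
not the fraction, so it is exposed as a parameter), the membership matrix
rebuilt and the tree re-aggregated per group; the deviation rate is the
maximum relative deviation of group composites from the full-panel
composite. Draws leaving any leaf unanswered are redrawn (bounded
retries). All randomness flows through one seeded generator; the published
±3.5 % figure depends on the unpublished raw questionnaire and is not
treated as a reproducible target.

**Cronbach's α** uses the variance formula with sample variances (ddof 1)
over complete respondent rows, raising when the total-score variance is
zero. The published α = 0.875 likewise depends on the raw questionnaire.

## Synthetic data

`generate_panel` draws each expert × leaf rating i.i.d. from the leaf's
*consensus distribution* — the exact object the membership stage
estimates — then thins cells to the leaf's response rate. This makes
parameter recovery a clean end-to-end check: with full response the
estimated membership row converges to the consensus vector (max abs
deviation < 0.02 at n = 5 000), and the composite converges to the
analytic W·(consensus)·V value. The default spec mirrors the case study's
conditions: 33 experts stratified 15/8/6/4 across regulator / producer /
testing / consumer-organization workplaces, the regulatory-capacity
consensus vectors taken from the bundled membership rows with response
rate 17/33, and the remaining blocks given consensus defaults whose
expected scores match their published dimension scores (the corporate
block centres on grade 3, the other two on ≈ 3.6).

What the generator deliberately does *not* model: respondent-level traits
or covariate effects — ratings are independent across cells, so inter-item
correlation is near zero and the synthetic Cronbach's α is small by
construction. Passing tests therefore demonstrate correctness of the
estimation and aggregation machinery, not that real panels behave like
i.i.d. raters; real questionnaires with consistent respondents will show
much higher α. `generate_raw_matrix` draws log-normal columns
exp(dispersion · z); dispersion 0 yields a constant column (exercising the
constant-column policy) and larger dispersion yields more skewed, more
informative columns, so entropy weights increase with dispersion.

## Problem sizes and determinism

The test and acceptance runs use the study-scale panel (33 experts, 18
leaves) for pipeline checks, 5 000 experts for recovery checks, 10
bootstrap groups at fraction 0.8, and batches of ~20 random 3–6
dimensional matrices for the formula-equivalence and AHP-recovery
properties. Every stochastic path takes an explicit seed; identical seeds
give bit-identical results.

## Known limitations

* The Likert→Saaty map is a convention; different maps give different AHP
  weights (the consistency test, not the map, is the guardrail).
* Group AHP aggregates mean scores rather than per-expert judgment
  matrices; geometric-mean-of-matrices aggregation is out of scope.
* Membership is purely frequency-based; no triangular/trapezoidal
  membership functions or higher-order fuzzy sets.
* The grade-band boundaries assume a linear normalization of the score
  axis; other anchorings of the 0–1 bands are not supported.
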