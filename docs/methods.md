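# Methods

`crdnet` implements, as a tested and configurable pipeline, a
machine-learning analysis of component-resolved diagnostics (CRD) data: serum
specific-IgE (sIgE) responses of children to ~112 allergen components
measured on a multiplex array (ISAC Standardised Units, ISU), related to
asthma. Birth-cohort CRD data are rarely publicly deposited, so the package
pairs every analysis stage with a synthetic cohort generator that reproduces
the *statistical shape* of such data, letting every claim be tested against
planted ground truth.

## Preprocessing

ISU values are dichotomised at the manufacturer cut-off: positive iff
strictly greater than 0.30 ISU (ties at 0.30 are negative). A component is
**active** when positive in at least 5% of participants (inclusive, with the
pre-filter participant count as denominator); participants are retained when
positive to at least one active component. Continuous analyses use
`log(x + 1)`.

Missing cells are rejected by default; `missing_to_zero=True` maps them to 0
(ISAC reports below-detection as 0) and logs the count. Both behaviours are
explicit because silent imputation hides data problems.

## Component clusters

Dependence between components is measured with Székely's distance
correlation (dCor), computed from double-centred pairwise-distance matrices
(`dCov² = mean(A∘B)`, `dCor = dCov/√(dVar_x·dVar_y)`), which detects
nonlinear as well as linear association. A constant column has dVar = 0 and
its dCor is defined as 0 (logged). The dissimilarity `1 − dCor` feeds
average-linkage (UPGMA) hierarchical clustering, cut at 0.40; clusters of
size one are flagged singletons. dCor is computed on `log(x+1)` values by
default (`dcor_on_log1=False` switches to raw ISU, whose heavy right tails
otherwise dominate the pairwise distances).

Robustness comparators: DIANA (Kaufman–Rousseeuw splinter splitting, always
dividing the largest-diameter cluster) and PAM (BUILD + SWAP k-medoids on the
precomputed dissimilarity; the SWAP phase never worsens the objective,
asserted at run time). Both are hand-implemented because no installed
library provides them on precomputed dissimilarities; `k` for both is set to
the agglomerative cluster count so the partitions are compared
like-for-like, with the plain (unadjusted) Rand index.

The connectivity graph uses all-pairs dCor for node connectivity
`k_i = Σ_{j≠i} dCor(i,j)` (scaled by the maximum), with a display-only edge
threshold (default dCor ≥ 0.3) that no statistic depends on.

## Sensitisation clusters

Participants are clustered on the Jaccard distance between binary profiles
with Ward linkage via the Lance–Williams recurrence on the precomputed
distances (the Ward.D2 convention; formally heuristic on a non-Euclidean
matrix but standard practice). The number of clusters is selected by the
Calinski–Harabasz index computed on the 0/1 profile coordinates (CH needs
centroids; the 0/1 embedding is the simplest faithful choice).

Cluster–outcome association uses a k×2 Pearson chi-square without Yates
correction (Monte-Carlo p-value conditional on margins when any expected
count is below 5), per-cluster odds ratios with Wald 95% CIs
(Haldane–Anscombe 0.5 correction on zero cells, flagged), and
Kruskal–Wallis for continuous outcomes. The OR reference group defaults to
all other retained participants and is switchable to a named cluster; no
multiple-testing adjustment is applied (results are reported raw).

## Pairwise density-ratio classification (JDINAC)

The classifier assumes class differences arise from *pairwise dependency*
changes. For each component pair (i, j), class-conditional joint densities
f¹ᵢⱼ and f⁰ᵢⱼ are estimated with a bivariate Gaussian product-kernel KDE and
the per-subject feature is `ln f¹ᵢⱼ/f⁰ᵢⱼ`, entered into an L1-penalised,
class-weighted logistic regression:

    logit P(Y=1|x) = α₀ + Σ_{i<j} β_ij ln [f¹ᵢⱼ(xᵢ,xⱼ) / f⁰ᵢⱼ(xᵢ,xⱼ)]

Estimation repeats T times (default 25): a stratified half-split; densities
on one half; features and the sparse logistic fit on the other; halves swap
(2T fitted models). The penalty is chosen per fit by 5-fold cross-validated
binomial deviance over a data-driven log-spaced grid with the
one-standard-error rule; class weights are inverse class frequency
normalised to mean 1. A pair's **differential weight** is the number of
models with β̂ᵢⱼ ≠ 0; pairs selected in ≥ 25% of models form the
differential network, with direction = sign of the mean nonzero β̂
(positive: the class-1 dependency pattern raises predicted risk).

Numerical choices that matter:

* **Out-of-sample predictions.** Each model scores the participants of its
  *density* half (never seen by its logistic fit). Kernel sums for those
  participants exclude their own kernel mass (leave-one-out) with the
  normalisation reduced to n−1: a participant's own kernel centred at their
  location inflates their class's density and would otherwise leak their
  label into the "out-of-sample" average.
* **Shared bandwidths across classes.** Per-component bandwidths (Scott's
  rule for d=2, `σ·n^(−1/6)`; Silverman and fixed rules available) are
  computed on the pooled density half and shared by both classes: the log
  ratio of two KDEs smoothed with different bandwidths is biased away from
  zero even when the class densities are identical.
* **Marginal normal scores.** Before density estimation each component is
  mapped through its rank-based normal scores (`Φ⁻¹(rank/(n+1))`, ties
  averaged; new data interpolates the stored training quantiles, clamped to
  the training range). The pair density *ratio* is invariant to monotone
  per-component transforms in population — Jacobians cancel — so this
  changes only estimation quality: on the skewed log-ISU scale a
  fixed-bandwidth KDE loses roughly 0.05 AUC against the optimal
  discriminant in planted-interaction simulations, and normal scores
  recover it. `marginal_transform="none"` restores plain log-scale
  estimation.
* **Density floor** 1e−10 before logs: features stay finite at the edge of
  the empirical support, and a point far from both classes' support gets
  feature exactly 0.
* Bandwidths are floored at 1e−3 (zero-inflated components can be
  near-constant in a class); splits that leave fewer than 5 participants of
  a class on a half are redrawn (bounded retries).

## Baseline and evaluation

The baseline is the same L1-penalised, class-weighted logistic regression on
individual component `log(x+1)` values. Both models are evaluated with
stratified K-fold cross-validation (default 10-fold) repeated R times
(default 50) with fresh shuffles; per-participant out-of-fold probabilities
are **averaged over repetitions** and the metric suite (AUC, accuracy,
sensitivity, specificity, precision, F1) is computed from the averaged
probabilities at the 0.5 threshold (configurable). AUC is the rank
statistic, which equals the trapezoid area under the ROC polygon. Precision
with zero predicted positives is reported as 0 with a warning. Every report
carries its protocol (folds, repetitions, seed, averaging mode), and model
comparisons refuse mismatched protocols. JDINAC's native half-split
averaging provides cross-validated probabilities without an outer CV; an
outer-CV wrapper (`repeated_cv_evaluate` with `model="jdinac"`) exists for
strictly held-out evaluation.

## Synthetic cohorts

`generate_cohort` draws from a Gaussian copula: a latent correlation matrix
built from a global "atopy" factor (loading λ on every component, so λ² is
the baseline between-component correlation), block-exchangeable correlation
for designated component blocks, and — in the `interaction_only` regime —
class-specific correlation overrides for designated pairs (PSD-checked,
with a named error on infeasible configurations). Latent scores map to ISU
via `exp(μ + σz) − shift` truncated at 0 (so below-detection zeros are
*correlated*, as in real assays), plus an optional independent
structural-zero mask. A "sensitisation-prone" gate shifts non-prone
children's latent scores down by a constant, concentrating positivity in
part of the cohort without raising between-component correlation — without
it, 44 components each ≥5% positive would make ~80% of the cohort positive
to something, far above the ~46% a real cohort shows.

Outcome regimes: `null` (independent Bernoulli), `marginal` (logistic in
chosen components' log values, intercept calibrated by bisection to the
target prevalence), and `interaction_only` (labels drawn first, latent layer
sampled class-conditionally: identical marginals, dependence-only signal —
precisely what a pairwise density-ratio model should detect and a
main-effects model cannot).

`reference_cohort_config()` freezes a cohort of 461 children × 112 components:
seven blocks of sizes (4,3,4,6,8,4,4) plus 11 active singletons and 68 rare
components, calibrated once so that across seeds ~43–44 components pass the
5% filter, ~46% of children are sensitised, and ~33% of the sensitised have
asthma (driven by a marginal effect on the mite-like block by default).
Default positivity among the prone spans ~15–55% per component.

What the generator does **not** emulate: assay noise floors and plate
effects, semi-quantitative ISU banding, longitudinal trajectories,
covariates (age, sex), and real cross-reactivity structure beyond block
correlation. Passing tests therefore demonstrate correctness of the
*methods* under controlled dependence structure, not clinical validity on
real cohorts.

## Pipeline

`pipeline.run` executes ingest → dichotomise/filter → component clusters →
sensitisation clusters → bipartite views → JDINAC vs baseline → differential
network, writing every stage's outputs plus `summary.json` and a SHA-256
manifest; runs are byte-deterministic for a fixed config and seed (timings
live only in the manifest). `pipeline.validate` re-runs the frozen pipeline
from scratch on a second dataset — deriving that dataset's own active set,
as a narrow external validation should — and reports the Jaccard overlap of
the two differential networks' edge sets; an "apply frozen model" path is
available through `jdinac.predict`.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the planted-recovery studies
at n = 300–461 participants, 8–112 components, T = 20 split repetitions and
5–20 seeds per claim, and the end-to-end determinism check with a reduced
protocol (T = 2, 5-fold × 1 CV); these sizes were chosen so the full suite
completes on a laptop-class single core while leaving each statistical band
comfortably estimable.

## Known limitations

* Differential-edge *strength* is not estimated (only selection counts and
  direction); higher-order (≥3-way) interactions are out of scope.
* Ward-on-Jaccard and CH-on-0/1-coordinates are pragmatic conventions, not
  exact geometry.
* The dCor connectivity graph's edge threshold is presentation-only.
* PAM's SWAP is the classic O(k·p²) search; fine for p ≤ a few hundred
  components, not tuned for larger feature sets.
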