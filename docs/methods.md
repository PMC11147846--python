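# Methods

This note documents the models, statistics and design choices behind
`fcbench`: what the null predictors and evaluation statistics compute, how
the synthetic cohorts are generated and calibrated, which numerical
conventions are used, and what the passing test suite does and does not
demonstrate about real data.

## Connectivity containers and conventions

A connectivity matrix is a symmetric p×p array tagged as functional
(`FC`: unit diagonal, off-diagonal in [−1, 1], positive semidefinite when
built from time series), streamline counts (`SC_counts`: nonnegative
integers, zero diagonal) or resampled structural weights. All edge-level
statistics operate on the canonical edge vector: the strict upper
triangle in row-major order, length p(p−1)/2. Using one triangle avoids
double-counting edges in correlations; the diagonal is excluded
everywhere. Parcels are 0-based internally and 1-based in written
reports. All off-diagonal edges enter correlations as-is, including
negative FC edges (treating them specially is contested, and dropping
them would change every statistic; the thresholded-graph centrality
analysis is where negative edges are removed, explicitly).

Cross-validation folds are built by a seeded shuffle followed by
contiguous blocks, remainder subjects distributed one per fold, so fold
sizes differ by at most one and the assignment is reproducible from
(n, k, seed).

## The null predictors

**avgFC** assigns each validation subject the mean eFC of the k−1
training folds. Under an exchangeable similarity structure with mean
inter-subject edge correlation ρ, its expected per-subject correlation is
√ρ (each subject = shared component + idiosyncratic deviation; the
training mean is nearly pure shared component). This is the "glass
ceiling": no information about the subject, yet √0.70 ≈ 0.84 per-subject
performance at anatomical granularity.

**navgFC** adds i.i.d. N(0, σ²) noise per upper-triangle edge,
independently per subject, mirrored to keep symmetry; the diagonal stays
1. Predictions are *not* clipped to [−1, 1] by default (clipping would
distort the tuned noise distribution; a flag enables it). Closed forms
used in tests: performance decreases monotonically in σ, and within a
fold corr(pred_i, pred_j) ≈ v/(v+σ²) with v the edge-variance of the
training mean. `tune_sigma` bisects σ to any target performance below the
ceiling (a target at/above the ceiling returns 0 or errors).

All per-subject noise streams derive from (seed, subject-index) so any
subject's prediction is individually reproducible.

## The MLP reference predictor

A fully connected feed-forward network maps resampled SC edge vectors to
FC edge vectors: `n_layers` weight layers (default 10) of `width` hidden
units (default 1024), ReLU activations, linear output, He initialization,
Adam. The output bias is initialized to the training-mean edge vector —
the minimizer of the accuracy term among constant predictors, and the
natural starting point for a model whose main risk is converging to the
group average anyway.

The loss trades prediction accuracy against collapse onto a common
pattern:

    L = (1−γ)·(1 − mean_i corr(pred_i, target_i))
        + γ·mean_{i≠j} corr(pred_i, pred_j)
        + λ·mean(W²),        γ = 0.4, λ = 0.01.

The published loss this emulates is not restated in the sources this
package follows; the surrogate matches its stated intent (accuracy term,
inter-individual-variation term, regularizer) and two-parameter form. The
gradient of the correlation terms with respect to the predicted batch is
analytic (for r = corr(x, y), ∂r/∂x = (ŷ − r·x̂)/‖x_c‖ with x̂, ŷ the
centered-normalized vectors), verified against finite differences at
1e−10; the loss-gradient is a pluggable hook so an alternative loss can
be swapped in without touching the training loop. Whether published
per-subject correlations use Fisher-z averaging is unknown; we average
raw correlations everywhere, consistently.

Training is full-batch by default, one model per fold, trained only on
that fold's training subjects; `predict` has a leakage guard that raises
if a prediction is requested for a subject in the model's training set.
Desk-scale configurations (width 256 / 2000 epochs via
`MLPConfig.desk_scale`, and smaller still in the analysis scripts: 4
layers, width 64, 150–200 epochs) are deliberate problem-size choices for
interactive runs; the published-scale values remain the defaults of the
config dataclass and are logged with every model.

## Gaussian resampling of streamline counts

Streamline counts span orders of magnitude and are zero-inflated. The
resampler draws one standard normal per upper-triangle edge, sorts the
draws, assigns them in rank order (smallest draw → smallest count), then
affinely rescales the off-diagonal entries to mean 0.5 and sd 0.1
*exactly* (standardize, then affine map — not reliant on the sample
moments of the draws), and mirrors to the lower triangle. Tied counts
(ubiquitously, zeros) receive the mean of the Gaussian order statistics
their rank group spans: deterministic given the draws, and equality of
tied edges is preserved. The diagonal stays 0 and is excluded from the
moments; whether the original procedure includes it is unstated, and
excluding it keeps the 0.5/0.1 contract exact on the quantities that
matter. Rank order is preserved (Spearman 1 on tie-free inputs), and for
tie-free inputs the output marginal is exactly rescaled Gaussian order
statistics.

## Evaluation statistics

* **Per-subject correlation**: Pearson over edge vectors; a constant
  prediction vector is flagged and reported as NaN rather than silently
  dropped. Degeneracy checks use a relative tolerance (a vector of
  identical values can carry ~1e−17 rounding jitter).
* **Concatenated R²**: squared Pearson correlation of the concatenated
  edge vectors. It is sign-blind (a perfectly anti-correlated prediction
  scores 1), which reports document. Note the two conventions do not
  convert into each other: a mean per-subject correlation of 0.84 and a
  concatenated R² of ~0.56 can coexist on the same data because the
  concatenated statistic pools within- and between-subject variance; we
  implement the concatenated convention literally and surface the
  discrepancy here rather than resolving it.
* **Preservation correlation**: across subject pairs, Pearson between
  inter-eFC and inter-prediction similarity. Undefined (NaN + warning)
  when inter-prediction similarities are constant, e.g. a single shared
  prediction. Invariant under adding a shared constant matrix to all
  predictions.
* **Network error map**: per subject and parcel, r = Pearson between that
  parcel's row of the prediction and of eFC, diagonal entry excluded;
  error = ln(1 − r), with r clipped at 1 − 1e−9 to keep perfect rows
  finite. Natural log is the convention that puts typical errors in the
  −1.7…−0.9 range familiar from published per-network tables (log10 would
  not). Parcel errors are averaged within each Yeo-7 network, then over
  subjects.

## Centrality analysis

FC is thresholded at significance level α = 10⁻⁴ on the edge correlation
coefficients: the critical |r| solves the two-sided t test with
T_eff − 2 degrees of freedom (r_crit ≈ 0.112 at T_eff = 1200); edges
below threshold, and surviving *negative* edges, are set to 0 (the
interpretability of negative correlations is disputed). Both the
two-sided choice and T_eff are configurable since the original convention
is not fully specified. Degree is computed on the binarized graph
(following the convention of the graph-metric literature the analysis
descends from; a flag switches to weighted), eigenvector and PageRank on
the weighted positive graph; on disconnected graphs eigenvector
centrality is computed on the largest component (zeros elsewhere,
flagged), and PageRank (damping 0.85, the conventional value) always sums
to 1 before rescaling. "z-scored and rescaled to [−1, 1]" is implemented
as z-score across the concatenation of all subjects' node values followed
by a linear min-max map onto [−1, 1] — an order-preserving composition,
so the variance-explained statistic (squared Pearson between individual
and cross-validated training-average centralities, concatenated over
subjects × nodes) is unaffected by the rescaling choice.

## Cognition battery

`predict_cognition` runs, per outer loop (default 10), a fresh seeded
k-fold split (default 10); per fold, a lasso is fitted on the training
folds with its penalty chosen by nested 3-fold cross-validation over a
log-spaced grid (the original penalty-selection procedure is unstated);
out-of-fold predictions are concatenated and correlated with the true
scores → one (r, p) per loop; the mean and variance of r and the median p
are reported (how per-loop p-values were originally combined into one
significance call is unstated, so we report them all and use the median).

Regressing out SC is per subject across edges: the residual of the
subject's FC edge vector on [1, SC edge vector] — this removes each
subject's FC∼SC linear dependence, which is the stated motive; the
per-edge-across-subjects alternative exists behind an explicit function
name. Residuals are mean-zero and orthogonal to the subject's centered SC
at 1e−10. The rpFC control reassigns predictions by a Sattolo cycle — a
seeded permutation that is guaranteed fixed-point-free, so no subject
keeps their own prediction.

Two desk-scale statistical points, both documented because they only bite
at small n:

* **Fold-mean artifact.** When the lasso selects nothing, each fold's
  prediction is the training mean of y, which is anti-correlated with the
  held-out fold mean; the concatenated correlation is then ≈ −1/√(fold
  size) with nominal p ≈ 0.002 *regardless of n*. Loops in which every
  fold predicts a constant are therefore flagged degenerate and reported
  as undefined, and the battery's significance call requires median
  p < 0.05 **and** positive mean r — predicting cognition means
  correlating positively with it. Under a global null this makes the
  false-positive rate conservative (≤ nominal) rather than exactly 0.05;
  the test suite checks it is controlled.
* **No multiple-testing correction** is applied across the ten variants
  (none is conventional in this analysis); reports annotate the 10-test
  family.

## The synthetic cohort generator

The generator's job is to emulate the second-order statistical structure
the analyses consume — not biophysics (no hemodynamics, no neural mass
dynamics).

**FC.** Each subject's latent correlation target is the Schur mixture

    C_i = (u uᵀ) ∘ G + (v vᵀ) ∘ R_i,      u_a² + v_a² = 1,

with G a shared network-structured template (factor model: one global
factor, one factor per functional system, parcel noise — within-network
correlations elevated), R_i a subject-specific random correlation matrix
of rank 5 (individual deviations are structured, not i.i.d. edge noise),
and v_a the per-parcel deviation amplitude. Because both Schur factors
are correlation matrices and u_a² + v_a² = 1, every C_i is exactly a
unit-diagonal PSD correlation matrix — no nearest-correlation projection
is needed (a projection applied to a raw additive mixture at p = 68 is
strongly active and distorts the intended deviation structure, which is
why the mixture form was chosen). Time series of length T are drawn as
Gaussian with covariance C_i and eFC computed as Pearson correlation, so
within-subject estimation noise enters exactly as in real parcellated
BOLD and the p = 10⁻⁴ threshold has a well-defined sampling distribution.

v_a = b · s_a, where s_a is the per-network sd multiplier (variance
multipliers LSN 2.2 > FPN = DMN 1.5 > VAN = DAN 1.1 > VN = SMN 0.7,
normalized to mean-square 1) — the ordering in which individual FC is
observed to deviate from the group average, limbic most, primary sensory
least. The global amplitude b is calibrated by bisection so the
*realized* mean inter-eFC of a pilot batch (30 subjects, common random
numbers across bisection evaluations so the pilot curve is smooth and
monotone in b) hits `rho_target` ± 0.008. Feasibility is checked at both
ends: a target above the finite-T ceiling (only reachable with zero
deviations) or below the maximal-deviation floor raises a calibration
error naming the parameter to change. The √ρ group-average consistency
(0.84² ≈ 0.70) is *not* imposed; it emerges from the exchangeable
structure and is asserted by tests.

Defaults: n = 100, p = 68 ("dk_like", 68 parcels in realistic Yeo-7
proportions), T = 1000, ρ_target = 0.70 — the anatomical-granularity
regime. A "schaefer_like" 200-parcel preset exists; its inter-eFC is not
directly reported anywhere we rely on, and the value implied by the
published group-average performance at that granularity (0.76² ≈ 0.58)
should be treated as an inference, so no default ρ_target is hard-wired
for it.

**SC.** Latent edge strength mixes the standardized template with the
subject's standardized FC deviation edges, weight `sc_coupling` = 0.8 on
the shared part; counts are round(exp(1.5 · normal-scores(latent) + 2.5 +
0.5 · ε)) — heavy-tailed (≥ 2 orders of magnitude spanned at every seed),
zero-inflated, symmetric, zero diagonal. The across-subject variance of
an SC edge is therefore mostly SC-private (log-noise ε) with a minority
share coupled to the subject's FC deviation: individual-level edgewise
SC→FC coupling is real but weak, matching the empirical regime in which
individual information demonstrably exists in both modalities
(fingerprinting works) yet trained SC→FC models fail to beat the group
average.

**Cognition.** y_i = Σ_k β_k · z(log(1 + SC edge feature k)) + noise,
with 5 seeded feature edges (chosen among above-median-strength edges so
none is all-zero), β = 0.6 each, noise sd 0.5. Features are standardized
on the log scale, where counts are approximately Gaussian — on the raw
scale the heaviest-tailed counts dominate the standardization and the
trait becomes unrecoverable by edge-sparse regression even given the true
feature columns. The trait loads *sparsely and strongly* on a handful of
connections deliberately: the analysis method the battery prescribes is
the lasso, and at desk-scale cohort sizes a lasso can only recover a
trait whose signal is concentrated enough to survive selection among
hundreds of candidate edges. β = 0 decouples cognition from connectivity
entirely (the global-null case used for false-positive-rate tests). A
simulation-oracle band for the default effect sizes (cross-validated
lasso r from SC ∈ [0.70, 0.95] at n = 200) was computed by brute force
before the analysis modules were built and is frozen in the tests.

**Seeds.** All streams (template, subjects, pilot, SC, cognition) derive
from one config seed via named SeedSequence children; cohorts are
bit-reproducible from their config, and written cohorts record the seed
in their manifest.

## What passing tests do and do not show

The generator matches the statistics the analyses consume: inter-subject
FC similarity and its network structure, heavy-tailed SC with weak
individual-level FC coupling, an SC-linked trait. It does not emulate
hemodynamics, autocorrelated BOLD noise, head-motion artifacts, site or
session effects, non-Gaussian FC tails, or the empirical SC topology
(small-worldness, distance dependence). Passing tests therefore show that
the *pipeline* is correct and that the headline phenomena (glass
ceiling at √ρ, navgFC mimicry, zero preservation, network-ordered errors,
centrality reproduction, the regress-out artifact in cognition
prediction) follow from the modeled similarity structure — not that any
particular human dataset has these exact numbers.

## Problem sizes

Analyses and tests run at deliberately chosen desk scales: the benchmark
cohort at n = 100, p = 68, T = 1000 (the calibration regime); Monte-Carlo
statements over 50 replicate cohorts; the cognition battery at n = 600 on
a 24-parcel atlas with a 4-layer width-64 MLP and 3 outer loops (the
dataclass defaults remain 10 loops and the published MLP scale); the
false-positive-rate check over 200 scaled-down replicates (n = 40, 30
features, one loop). These sizes are the package's own choices for
interactive reproducibility; every size is a visible parameter.

## Known limitations

* The MLP loss is a surrogate for an unpublished exact form; conclusions
  about "the" published model transfer only insofar as the surrogate
  matches its intent.
* The concatenated-R² vs per-subject-correlation tension (above) is
  surfaced, not resolved.
* The battery's significance rule is deliberately conservative under
  degenerate fits; exact nominal calibration of the two-sided Pearson
  test does not hold at desk-scale fold sizes (fold-mean artifact).
* The schaefer_like regime's inter-subject similarity is an inference,
  not a reported value.
* `tune_sigma` assumes monotone performance in σ (true for this noise
  model) and tunes to mean per-subject correlation only.
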