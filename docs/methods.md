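# Methods

This note documents the statistical models implemented in `flibiome`, the
generative model behind the synthetic cohorts, the numerical choices, and
the known limitations. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Fatty Liver Index

`compute_fli` evaluates the Bedogni et al. index: linear predictor
`L = 0.953·ln(TG) + 0.139·BMI + 0.718·ln(GGT) + 0.053·waist − 15.745`
(triglycerides in mg/dL, GGT in U/L, waist in cm), mapped through
`FLI = 100·expit(L)`, so FLI is strictly inside (0, 100). A
`TG_MMOL_TO_MGDL = 88.57` constant is provided for SI-unit data but never
applied silently. Group assignment supports two schemes: the main
contrast low (< 60) vs high (≥ 60), and an alternative low (< 30) vs high
(≥ 60) with intermediates labelled `excluded`. Boundaries are inclusive
on the high side (`FLI = 60` is high) and exclusive below (`FLI = 30` is
not low), matching the printed inequalities. For the ML path, FLI and
self-reported alcohol are mean-imputed — by the training-partition means
when `means=` is supplied, to avoid information leaking from test rows;
linear-model stages use listwise deletion; the liver-specific dissection
drops rows missing GGT/TG/BMI and never imputes them.

## Filtering

Taxa are retained when seen with more than `min_count` (default 3) reads
in at least `min_prevalence` (default 1%) of samples **and** their
coefficient of variation across all samples exceeds `cv_threshold`
(default 3). The CV rule's direction is genuinely ambiguous in the
literature this convention descends from (the variance filter is usually
"keep high-CV taxa", but the rule is sometimes printed as "filter taxa
with CV ≤ 3", which is the same thing, and sometimes read the other way);
we keep high-CV taxa by default and expose both the threshold and the
direction (`cv_keep_above`). Samples with fewer than 50,000 reads
(strictly less), pregnant participants, and participants with antibiotic
use within 6 months are removed.

## Balance transform

`philr_transform` prunes the provided rooted tree to the observed taxa,
requires strict binarity (multifurcations are rejected, not silently
resolved — the balance definition needs exactly two child clades), names
unnamed internal nodes `n1, n2, …` in preorder, and computes per node
`b = sqrt(rs/(r+s)) · ln(g(x_R)/g(x_S))`, numerator = first child in the
stored tree. The pseudocount (default 1) is applied to zero cells only,
mirroring the transform's convention of imputing absent taxa; an
all-cells option exists. Unweighted coordinates only — no branch-length
or abundance weighting. Pruning before or after the pseudocount is
mathematically irrelevant here because the pseudocount only touches cells
of retained taxa. Properties guaranteed by construction and verified by
oracle tests: balances per tree = taxa − 1; flipping a node's children
negates exactly that balance; compositional scale invariance; Euclidean
distance in balance space equals Aitchison (CLR) distance. The CLR
transform adds its pseudocount to all cells (its formula is
`ln(x+pc) − mean ln(x+pc)`), so the isometry is exact when compositions
are zero-free.

## Diversity, ordination, regression

Shannon diversity is computed in nats as the mean of 10 random
rarefactions (without replacement, multivariate hypergeometric) to the
minimum retained sample depth by default — the rarefaction depth is
otherwise a free choice and is configurable. Group differences are
modelled by a binomial GLM of the high-FLI indicator on Shannon + age +
sex + alcohol (listwise deletion; separation is flagged in the summary
rather than returned silently). Beta diversity is the Euclidean geometry
of the balances summarized by centered, **unscaled** PCA (balances share
the log-ratio scale; scaling would distort the distance structure), with
a deterministic sign convention (largest-|loading| entry positive).
log10(FLI) is regressed by OLS on the first three PCs + sex + age +
alcohol; zero-variance PC columns are dropped so the model nests down to
the covariates-only fit; collinear designs raise.

## Differential abundance

The ALDEx2-style procedure: for each of `n_mc` Monte-Carlo instances
(default 128) every sample's composition is drawn from
Dirichlet(counts + 0.5), CLR-transformed, and a Welch's t-test compares
the groups per taxon with Benjamini–Hochberg correction across taxa
within the instance. The reported Q is the expectation (mean) of the
adjusted p across instances — the cited tool's aggregation; the effect is
the median over instances of the difference in group-median CLR
abundance, signed so positive = higher in the high-FLI group. The
`n_mc = 128` and prior 0.5 defaults follow the tool's conventions (the
number of instances and prior are not dictated by the analysis itself);
both are configurable. Discovery threshold Q < 0.001.

## Machine-learning architecture

- **Split.** 70/30, stratified by sex × region: within each stratum,
  `round(0.7·n)` samples train (always within one sample of the target
  fraction), deterministic under the seed.
- **LOGOCV.** One partition per region; a region's rows never enter its
  own model's training, feature selection, or fold-validation. Row-level
  provenance is kept on the bundle so the no-leakage property is
  assertable.
- **Feature selection.** Per fold, a random forest (default 500 trees,
  `sqrt` features) is fit and every feature ranked by out-of-bag
  permutation importance: per tree, the drop in OOB accuracy (or rise in
  OOB MSE) when the feature's values are permuted, averaged over trees —
  the classic randomForest mean-decrease-in-accuracy scheme, which we
  implement directly because scikit-learn exposes no OOB variant (each
  tree's bootstrap sample is reconstructed exactly from its
  `random_state`). Ties break by feature name for determinism. The final
  set is the plain intersection of the per-fold top-k (default 50) lists,
  ordered by mean rank; an empty intersection is returned with the
  per-fold lists, not raised. Forest size and permutation repeats
  (default 5) are free choices, exposed as parameters.
- **Hyperparameter search.** A Gaussian-process surrogate (Matern 5/2 +
  white noise, unit-cube coordinates) with expected-improvement
  acquisition over the box: eta [0.001, 0.3], gamma [0.1, 5], max_depth
  [2, 8], min_child_weight [1, 10], subsample [0.2, 0.8],
  colsample_bytree [0.2, 0.9], nrounds [50, 5000]; 30 random preliminary
  rounds then 100 guided rounds by default. Integer parameters are
  rounded at evaluation. The objective is the mean LOGOCV validation
  metric (AUC for classification, RMSE for regression). Published optima
  for both tasks ship as ready defaults (`HyperParams.classification_default()`).
- **Variants.** Sensitivity bundles restrict columns to covariates only
  (age, sex — alcohol is offered to the selector but is a pre-selection
  input, not a guaranteed covariate) or balances only. A stricter
  region-independent variant re-runs selection (LOGOCV over the remaining
  five regions) and optimization (six randomized 70/30 splits of the
  region-free training rows) separately per model, so each model's
  features and parameters owe nothing to its validation region.
- **Validation.** Internally, each model is scored only on its omitted
  region's rows in the test partition (AUC, AUPRC with the positive
  prevalence as baseline, ROC/PR curves; RMSE/R² for regression).
  Externally, a new cohort is pushed through the identical transform:
  counts subset to the training taxa, unobserved taxa at pseudocount 1 —
  so every training balance name resolves by construction — then scored
  per model and as the six-model-averaged prediction (one averaged
  ROC/PR curve). Applying a bundle to its own test cohort through the
  external path reproduces the internal metrics exactly, because the
  balance transform is per-sample deterministic.

## Interpretation

Partial dependence of a feature at value v is the mean predicted
high-FLI probability over evaluation rows (each model's own training
fold by default; configurable) with the feature clamped to v; the default
grid is the observed quantiles plus min/max, collapsing to the unique
values for discrete features. The relative effect is the median across
the six models of PD(max) − PD(min); because the underlying phrasing of
this estimator admits two readings, both the signed medians and the raw
per-model (PD-min, PD-max) pairs are reported. The liver-specific
dissection strata participants into 18 categories (age <40 / 40–60 / ≥60
× sex × BMI <25 / 25–30 / ≥30, half-open bins so 40, 60, 25 and 30 fall
in the upper bin), fits random-forest regressors for GGT and
triglycerides over the LOGOCV folds within each stratum (strata under 50
participants or with a single region are skipped with a warning), takes
per-category top-k intersections, and intersects the union over
categories with the FLI feature set.

## Synthetic-cohort generator

The generator is the package's stand-in for restricted population-survey
data and defines the study conditions the tests run under.

A single standard-normal latent liver score `z` ties covariates,
microbiome, and outcome together:
`z = 0.30·z_age + 0.30·sex(±1) + 0.905·ε`. The four FLI components are
linear-Gaussian in `z` (ln TG: mean 4.70, loading 0.35, residual SD 0.28;
BMI: 26.0 / 3.2 / 2.4; ln GGT: 3.40 / 0.50 / 0.40; waist: loading 7.0,
residual SD 6.0 cm). These centers and spreads are plausible for a
middle-aged northern-European population sample (median TG ≈ 110 mg/dL,
GGT ≈ 30 U/L, mean BMI 26); the exact survey distributions are not
published at that granularity, so they are defaults, exposed in
`CovariateParams`. The waist mean is then **calibrated in closed form**
(not by trial): under the model the linear predictor L is Gaussian with
known mean and SD, so the location shift putting `P(FLI ≥ 60)` at the
configured target (default 0.30, the cohort's approximate high-FLI
share) is analytic. Age is truncated-normal 50 ± 13 on [25, 74]; sex a
fair coin; alcohol lognormal with a 25% zero share; pregnancy (3% of
women under 45) and antibiotics (5%) flags drive the exclusion filters;
read depth is lognormal (median 1e5, σ = 0.35) so a realistic few percent
fall under the 50,000-read cutoff.

Counts are Dirichlet-multinomial: per-taxon baseline log-abundances
~ N(0, 2), small per-region shifts (SD 0.15) so geography is a real
nuisance factor, concentration 200 for metagenome-like overdispersion,
and each planted clade adds `+effect·z` to the log-abundance of its
node's first-child leaves and `−effect·z` to the second-child leaves —
so exactly that node's balance carries the signal, in the positive
direction. The truth record stores planted nodes, effects, leaf sets and
the latent scores. Trees are random coalescent-style joins (unbiased
topologies, no reference-database dependency) with deterministic preorder
internal names.

What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic autocorrelation of abundances, diet and medication effects,
batch/extraction artifacts, non-Gaussian covariate tails, and
FLI-component measurement error. Passing tests therefore demonstrate
that the machinery recovers planted, region-invariant signal under
realistic compositional noise — not that any particular clade-liver
association holds in people.

## Problem sizes

The test suite and acceptance script run scaled-down versions of each
stage, chosen to exercise the full architecture on one CPU: transform
oracles on 100 random tables (≤ 32 taxa, ≤ 50 samples);
differential-abundance calibration with 200 taxa, 100 + 100 samples,
64 Monte-Carlo instances over 10–20 seeds; the ML pipeline on cohorts of
n = 2000 with 201 taxa (200 balances), 5 planted clades (effect 1.0 per
unit z), selection forests of 100 trees with 2 permutation repeats, and a
reduced optimization budget of 5 random + 10 guided rounds over the
standard box with nrounds capped at 300. Defaults in the API remain the
full-scale values.

## Known limitations

- The GP/EI optimizer maximizes acquisition by candidate sampling (512
  uniform candidates per round), not gradient refinement; adequate for
  the 7-dimensional box, but optima are approximate.
- Permutation importance is computed per tree on OOB rows; features used
  by no tree get exactly zero importance, so extremely weak signals can
  tie at zero and be ordered alphabetically.
- `region_independent_variant` optimizes on randomized splits of the
  reduced training partition; with very small regions the nested
  validation folds can be imbalanced.
- The CLI covers simulation, FLI, transforms, diversity and differential
  abundance; the ML stages are library-first (they return rich Python
  objects — bundles serialize via `ModelBundle.save/load`).
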