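# flibiome

Tools for linking gut-microbiome composition to the **Fatty Liver Index
(FLI)** in population cohorts: index computation, phylogenetic balance
transforms, diversity and differential-abundance statistics, and
geography-aware gradient-boosting models with interpretable feature
selection. Written for microbiome epidemiologists who have a species-level
shotgun count table, a phylogeny over those species, and routine clinical
covariates — and who want robust, cross-region-validated associations
between microbial clades and likely hepatic steatosis.

## The science in brief

**FLI** (Bedogni et al.) estimates the likelihood of fatty liver from four
routine measurements. With the linear predictor

```
L = 0.953·ln(TG mg/dL) + 0.139·BMI + 0.718·ln(GGT U/L) + 0.053·waist cm − 15.745
FLI = 100·e^L / (1 + e^L)
```

FLI ≥ 60 rules steatosis in; FLI < 30 rules it out.

**Phylogenetic balances (PhILR).** Instead of fixed taxonomic ranks, read
counts are transformed into one coordinate per internal node *k* of a
rooted binary phylogeny. With child-clade leaf sets R and S (sizes r, s)
and g(·) the geometric mean of the pseudocounted relative abundances,

```
b_k = sqrt(rs / (r+s)) · ln( g(x_R) / g(x_S) )
```

This is an orthonormal log-ratio basis: it respects the compositional
nature of sequencing data, and Euclidean distances between balance vectors
equal Aitchison (CLR) distances. A positive balance means the numerator
clade is the more abundant; flipping numerator and denominator just flips
the sign.

**Modelling architecture.** A stratified 70/30 split (preserving sex ×
region balance) is followed by leave-one-group-out cross-validation over
the geographic regions: one gradient-boosted model per omitted region.
Features are chosen as the *intersection* of per-fold top-50 random-forest
out-of-bag permutation-importance lists; hyperparameters come from a
Bayesian (GP surrogate + expected improvement) search of the boosting
box. Each model is validated only on its own omitted region within the
held-out test partition, and can be applied to an external cohort through
the identical balance transform with a pseudocount of 1 for unobserved
taxa, so every balance name resolves. Interpretation uses partial
dependence (relative effect = median across models of PD at the feature's
max minus PD at its min) and a liver-specific dissection: features
predictive of GGT or triglycerides within 18 age × sex × BMI strata,
intersected with the FLI-predictive set.

Because population cohort data of this kind are access-restricted, the
package ships a first-class synthetic-cohort generator
(`flibiome.simulate`) emulating the study conditions: six regions, ~30%
high-FLI prevalence, covariates driving a latent liver score, and planted
clade–liver associations with a recorded ground truth.

## Worked example

```python
import flibiome as fb

# synthetic cohort: 6 regions, planted clade-liver associations
tree  = fb.generate_tree(64, seed=7)
nodes = fb.pick_planted_nodes(tree, 3, seed=7)
cfg   = fb.SimConfig(n_taxa=64, n_samples=1000, seed=7,
                     planted_clades=[(n, 1.0) for n in nodes])
counts, cohort, tree, truth = fb.generate_cohort(cfg, tree=tree)

groups = fb.assign_groups(fb.compute_fli(cohort))          # FLI >= 60 vs < 60
print("high-FLI prevalence:", round((groups == 'high').mean(), 3))

bal   = fb.philr_transform(counts, tree)                   # balances
X     = fb.assemble_features(bal.values, cohort)           # + age, sex, alcohol
y     = (groups == "high").astype(float)
split = fb.stratified_split(cohort, 0.7, seed=7)
parts = fb.logocv_partitions(split, cohort)

sel = fb.select_features(parts, X, y, top_k=20, n_trees=100, seed=7)
print("planted balances recovered:",
      sum(n in sel.features for n in nodes), "of", len(nodes))

params = fb.HyperParams(eta=0.1, gamma=0.5, max_depth=4, min_child_weight=2,
                        subsample=0.7, colsample_bytree=0.8, nrounds=150)
bundle = fb.train_bundle(parts, X, y, sel.features, params, seed=7)
report = fb.evaluate_internal(bundle, split, X, y, cohort)
print("mean cross-region AUC:", round(report.mean_auc, 3),
      "| AUPRC:", round(report.mean_auprc, 3),
      "(baseline", round(float(report.per_region['baseline'].mean()), 3), ")")
```

Output:

```
high-FLI prevalence: 0.293
planted balances recovered: 3 of 3
mean cross-region AUC: 0.916 | AUPRC: 0.826 (baseline 0.258 )
```

The prevalence sits at the calibrated ~0.30 target; the top-20 intersect
recovers every planted balance; and the cross-region AUC is far above the
covariate-only level because the planted microbial signal is
region-invariant. On a null cohort (no planted clades) the balances-only
AUC collapses to ~0.5.

A `flibiome` CLI wraps the same stages (`simulate`, `fli`, `transform`,
`alpha`, `beta`, `diffabund`); see `flibiome --help`.

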