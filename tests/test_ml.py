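"""Splits, LOGOCV, feature selection, optimization, training, validation."""

import numpy as np
import pandas as pd
import pytest

import flibiome as fb
from flibiome.ml import (
    DEFAULT_SEARCH_SPACE,
    HyperParams,
    _classification_metrics,
    _variant_columns,
)


class TestStratifiedSplit:
    def test_full_fraction_empties_test(self, planted_sim):
        split = fb.stratified_split(planted_sim["cohort"], frac=1.0, seed=0)
        assert len(split.test_ids) == 0
        assert len(split.train_ids) == len(planted_sim["cohort"])

    def test_per_stratum_allocation_within_one_sample(self, planted_sim):
        cohort = planted_sim["cohort"]
        split = fb.stratified_split(cohort, frac=0.7, seed=3)
        for (sex, region), idx in cohort.groupby(["sex", "region"]).groups.items():
            got = len(split.train_ids.intersection(idx))
            assert abs(got - 0.7 * len(idx)) <= 1

    def test_deterministic_disjoint_exhaustive(self, planted_sim):
        cohort = planted_sim["cohort"]
        s1 = fb.stratified_split(cohort, seed=5)
        s2 = fb.stratified_split(cohort, seed=5)
        assert list(s1.train_ids) == list(s2.train_ids)
        assert len(s1.train_ids.intersection(s1.test_ids)) == 0
        assert len(s1.train_ids) + len(s1.test_ids) == len(cohort)

    def test_invalid_fraction(self, planted_sim):
        with pytest.raises(ValueError):
            fb.stratified_split(planted_sim["cohort"], frac=0.0)


class TestLogoPartitions:
    def test_one_partition_per_region_none_in_own_fold(self, planted_sim):
        cohort, split = planted_sim["cohort"], planted_sim["split"]
        parts = fb.logocv_partitions(split, cohort)
        assert len(parts) == 6
        for part in parts:
            regions_in_train = set(cohort.loc[part.train_ids, "region"])
            assert part.region not in regions_in_train  # leakage guard
        # holdouts partition the training set exactly
        all_holdout = sum((list(p.holdout_ids) for p in parts), [])
        assert sorted(all_holdout) == sorted(split.train_ids)

    def test_two_region_cohort_gives_two_partitions(self, planted_sim):
        cohort = planted_sim["cohort"].copy()
        cohort["region"] = np.where(cohort["region"] <= 3, 1, 2)
        split = fb.stratified_split(cohort, seed=1)
        parts = fb.logocv_partitions(split, cohort)
        assert len(parts) == 2

    def test_single_region_rejected(self, planted_sim):
        cohort = planted_sim["cohort"].copy()
        cohort["region"] = 1
        split = fb.stratified_split(cohort, seed=1)
        with pytest.raises(ValueError, match="2 regions"):
            fb.logocv_partitions(split, cohort)


class TestSelectFeatures:
    def _noise_design(self, n=300, p=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)])
        X = pd.DataFrame(
            rng.normal(size=(n, p)), index=idx,
            columns=[f"f{j:02d}" for j in range(p)],
        )
        y = pd.Series(rng.integers(0, 2, n).astype(float), index=idx)
        regions = pd.Series(rng.integers(1, 7, n), index=idx)
        cohort = pd.DataFrame({"region": regions, "sex": "F"}, index=idx)
        split = fb.SplitPlan(train_ids=idx, test_ids=pd.Index([]), frac=1.0, seed=0)
        parts = fb.logocv_partitions(split, cohort)
        return X, y, parts

    def test_perfect_predictor_always_retained(self):
        X, y, parts = self._noise_design()
        X["oracle"] = y  # deterministic copy of the label
        sel = fb.select_features(parts, X, y, top_k=5, n_trees=30, n_repeats=2, seed=1)
        assert "oracle" in sel.features
        for top in sel.top_lists.values():
            assert "oracle" in top

    def test_top_k_equal_to_feature_count_returns_everything(self):
        X, y, parts = self._noise_design(p=12)
        sel = fb.select_features(
            parts, X, y, top_k=12, n_trees=20, n_repeats=1, seed=2
        )
        assert sorted(sel.features) == sorted(X.columns)

    def test_pure_noise_intersect_nearly_empty(self):
        X, y, parts = self._noise_design(n=500, p=60, seed=3)
        sel = fb.select_features(
            parts, X, y, top_k=10, n_trees=40, n_repeats=2, seed=3
        )
        assert len(sel.features) < 5  # << top_k across 6 independent folds

    def test_planted_balances_rank_first(self, planted_sim, small_bundle):
        sel = small_bundle["selection"]
        recovered = [nd for nd in planted_sim["nodes"] if nd in sel.features]
        assert len(recovered) == len(planted_sim["nodes"])


class TestHyperParams:
    def test_shipped_defaults_lie_inside_the_search_space(self):
        HyperParams.classification_default().validate()
        HyperParams.regression_default().validate()

    def test_out_of_range_rejected(self):
        bad = HyperParams(eta=0.5, gamma=1.0, max_depth=4, min_child_weight=2,
                          subsample=0.5, colsample_bytree=0.5, nrounds=100)
        with pytest.raises(ValueError, match="eta"):
            bad.validate()


class TestOptimizeHyperparams:
    SPACE = {**DEFAULT_SEARCH_SPACE, "eta": (0.01, 0.3), "nrounds": (20, 80)}

    def test_params_in_range_best_not_worse_than_random(self, planted_sim, small_bundle):
        sim = planted_sim
        feats = small_bundle["selection"].features
        best, trace = fb.optimize_hyperparams(
            sim["partitions"][:3], sim["X"], sim["y"], feats,
            space=self.SPACE, n_random=3, n_iter=3, seed=4,
        )
        best.validate(self.SPACE)
        random_best = trace.trace.query("phase == 'random'")["value"].min()
        assert trace.best_value <= random_best
        assert trace.trace.shape[0] == 6

    def test_deterministic_under_seed(self, planted_sim, small_bundle):
        sim = planted_sim
        feats = small_bundle["selection"].features[:5]
        runs = [
            fb.optimize_hyperparams(
                sim["partitions"][:2], sim["X"], sim["y"], feats,
                space=self.SPACE, n_random=2, n_iter=2, seed=9,
            )[0]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_budget_validation(self, planted_sim):
        with pytest.raises(ValueError):
            fb.optimize_hyperparams(
                planted_sim["partitions"], planted_sim["X"], planted_sim["y"],
                ["age"], n_random=0, n_iter=5,
            )


class TestTrainAndEvaluate:
    def test_variant_column_rules(self):
        feats = ["n3", "n8", "age", "sex"]
        assert _variant_columns(feats, "full") == feats
        assert _variant_columns(feats, "covariates-only") == ["age", "sex"]
        assert _variant_columns(feats, "balances-only") == ["n3", "n8"]
        with pytest.raises(ValueError):
            _variant_columns(feats, "everything")

    def test_missing_feature_raises(self, planted_sim, small_bundle):
        sim = planted_sim
        with pytest.raises(ValueError, match="absent"):
            fb.train_bundle(sim["partitions"], sim["X"], sim["y"],
                            ["not_a_column"], small_bundle["params"])

    def test_perfectly_separable_signal_saturates_auc(self, planted_sim):
        sim = planted_sim
        X = sim["X"].copy()
        X["oracle"] = sim["y"]
        params = HyperParams(eta=0.3, gamma=0.1, max_depth=2, min_child_weight=1,
                             subsample=0.8, colsample_bytree=0.9, nrounds=60)
        bundle = fb.train_bundle(sim["partitions"], X, sim["y"], ["oracle"], params)
        rep = fb.evaluate_internal(bundle, sim["split"], X, sim["y"], sim["cohort"])
        assert rep.mean_auc > 0.999

    def test_full_model_beats_restricted_variants(self, planted_sim, small_bundle):
        sim = planted_sim
        feats = small_bundle["selection"].features
        params = small_bundle["params"]
        reports = {}
        for variant in ("full", "covariates-only", "balances-only"):
            bundle = fb.train_bundle(
                sim["partitions"], sim["X"], sim["y"], feats, params,
                variant=variant, seed=1,
            )
            rep = fb.evaluate_internal(bundle, sim["split"], sim["X"], sim["y"],
                                       sim["cohort"])
            reports[variant] = rep.mean_auc
        assert reports["full"] >= reports["covariates-only"] - 0.02
        assert reports["full"] >= reports["balances-only"] - 0.02
        assert reports["full"] > 0.7

    def test_auprc_baseline_equals_prevalence_exactly(self, planted_sim,
                                                      small_bundle):
        sim = planted_sim
        rep = fb.evaluate_internal(small_bundle["bundle"], sim["split"], sim["X"],
                                   sim["y"], sim["cohort"])
        region = sim["cohort"].loc[sim["split"].test_ids, "region"]
        for r, row in rep.per_region.iterrows():
            ids = sim["split"].test_ids[region == r]
            assert row["baseline"] == pytest.approx(sim["y"].loc[ids].mean(),
                                                    abs=1e-12)

    def test_perfect_predictions_hit_unit_metrics(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        m = _classification_metrics(y, y)
        assert m["auc"] == 1.0 and m["auprc"] == 1.0
        assert m["baseline"] == pytest.approx(0.5)


class TestRegionIndependentVariant:
    def test_selection_never_sees_validation_region(self, planted_sim):
        sim = planted_sim
        space = {**DEFAULT_SEARCH_SPACE, "nrounds": (20, 60)}
        bundle, rep = fb.region_independent_variant(
            sim["split"], sim["X"], sim["y"], sim["cohort"], space=space,
            top_k=10, n_trees=20, n_repeats=1, n_random=2, n_iter=1,
            n_nested_splits=6, seed=2,
        )
        cohort = sim["cohort"]
        for part in bundle.partitions:
            assert (cohort.loc[part.train_ids, "region"] != part.region).all()
        assert bundle.per_model_features is not None
        assert len(bundle.models) == 6
        assert set(rep.per_region.index) <= set(cohort["region"])
        assert ((rep.per_region["auc"] >= 0) & (rep.per_region["auc"] <= 1)).all()


class TestRegressionTask:
    def test_continuous_fli_models_report_rmse_and_r2(self, planted_sim,
                                                      small_bundle):
        sim = planted_sim
        y = np.log10(sim["fli"].fli)
        params = HyperParams(eta=0.1, gamma=0.5, max_depth=3, min_child_weight=2,
                             subsample=0.7, colsample_bytree=0.8, nrounds=120)
        feats = small_bundle["selection"].features
        bundle = fb.train_bundle(sim["partitions"], sim["X"], y, feats, params,
                                 task="regression", seed=1)
        rep = fb.evaluate_internal(bundle, sim["split"], sim["X"], y,
                                   sim["cohort"])
        assert {"rmse", "r2"} <= set(rep.per_region.columns)
        assert (rep.per_region["rmse"] > 0).all()
        # planted signal: predictions explain real variance out of region
        assert rep.per_region["r2"].mean() > 0.2
        assert rep.mean_rmse < y.std()  # beats the trivial mean predictor

    def test_regression_objective_minimizes_rmse(self, planted_sim,
                                                 small_bundle):
        sim = planted_sim
        y = np.log10(sim["fli"].fli)
        space = {**DEFAULT_SEARCH_SPACE, "nrounds": (20, 60)}
        best, trace = fb.optimize_hyperparams(
            sim["partitions"][:2], sim["X"], y,
            small_bundle["selection"].features[:5], space=space,
            n_random=2, n_iter=1, seed=3, task="regression",
        )
        best.validate(space)
        assert (trace.trace["value"] > 0).all()  # RMSE scale, not -AUC


class TestBundleSerialization:
    def test_roundtrip_preserves_predictions(self, planted_sim, small_bundle,
                                             tmp_path):
        sim, bundle = planted_sim, small_bundle["bundle"]
        bundle.save(tmp_path / "bundle")
        assert (tmp_path / "bundle" / "bundle.json").exists()
        back = fb.ModelBundle.load(tmp_path / "bundle")
        assert back.feature_columns == bundle.feature_columns
        assert sorted(map(str, back.regions)) == sorted(map(str, bundle.regions))
        r = bundle.regions[0]
        X = sim["X"].iloc[:25]
        np.testing.assert_allclose(
            back.predict_scores(r, X), bundle.predict_scores(r, X), atol=1e-7
        )


class TestExternalValidation:
    def test_own_test_cohort_reproduces_internal_metrics_exactly(
        self, planted_sim, small_bundle
    ):
        sim, bundle = planted_sim, small_bundle["bundle"]
        internal = fb.evaluate_internal(bundle, sim["split"], sim["X"], sim["y"],
                                        sim["cohort"])
        external = fb.external_validate(
            bundle,
            sim["counts"][sim["split"].test_ids],
            sim["cohort"].loc[sim["split"].test_ids],
            sim["tree"],
            list(sim["counts"].index),
        )
        # identical floats, not merely close: same transform, same models
        assert (internal.per_region["auc"] == external.per_region["auc"]).all()
        assert (internal.per_region["auprc"] == external.per_region["auprc"]).all()
        assert external.averaged is not None

    def test_missing_training_taxon_still_yields_all_balances(
        self, planted_sim, small_bundle
    ):
        sim, bundle = planted_sim, small_bundle["bundle"]
        test_ids = sim["split"].test_ids
        counts = sim["counts"][test_ids].drop(index=sim["counts"].index[0])
        rep = fb.external_validate(
            bundle, counts, sim["cohort"].loc[test_ids], sim["tree"],
            list(sim["counts"].index),
        )
        assert len(rep.per_region) > 0  # every balance name resolved

    def test_unresolvable_feature_named_in_error(self, planted_sim, small_bundle):
        sim = planted_sim
        bundle = small_bundle["bundle"]
        # drop a needed taxon from the *training taxa* list: the balance
        # names shift and the bundle's features become unresolvable
        taxa = list(sim["counts"].index)[: sim["counts"].shape[0] // 2]
        with pytest.raises(ValueError):
            fb.external_validate(
                bundle, sim["counts"][sim["split"].test_ids],
                sim["cohort"].loc[sim["split"].test_ids], sim["tree"], taxa,
            )
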