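"""Geography-aware gradient-boosting models of the Fatty Liver Index.

The architecture:

1. stratified 70/30 train/test split preserving sex x region balance;
2. leave-one-group-out cross-validation (LOGOCV) over the regions inside
   the training partition — one model per omitted region;
3. feature selection: per LOGOCV subset, a random forest with out-of-bag
   permutation importance ranks all features; the simple intersection of
   the top-k (default 50) lists across subsets is the shared feature set;
4. Bayesian (GP surrogate, expected improvement) hyperparameter search of
   the gradient-boosted trees, scored as the mean LOGOCV validation
   metric (AUC for classification, RMSE for regression);
5. final models trained per LOGOCV subset, validated region-wise on the
   held-out test partition, and optionally applied to an external cohort
   through the same balance transform with a pseudocount for unobserved
   taxa.

Sensitivity variants restrict the design to covariates only (age, sex) or
balances only.  A stricter region-independent variant redoes selection and
optimization separately per model with the validation region fully
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from xgboost import XGBClassifier, XGBRegressor

from .fli import compute_fli, assign_groups
from .importance import oob_permutation_importance, rank_features
from .optimize import minimize_ei
from .transform import PhilrTransform

__all__ = [
    "DEFAULT_SEARCH_SPACE",
    "CLASSIFICATION_OPTIMA",
    "REGRESSION_OPTIMA",
    "HyperParams",
    "SplitPlan",
    "LogoPartition",
    "FeatureSelection",
    "ModelBundle",
    "MetricsReport",
    "assemble_features",
    "stratified_split",
    "logocv_partitions",
    "select_features",
    "optimize_hyperparams",
    "train_bundle",
    "evaluate_internal",
    "region_independent_variant",
    "external_validate",
]

#: Search box for the boosted-tree hyperparameters.
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "eta": (0.001, 0.3),
    "gamma": (0.1, 5.0),
    "max_depth": (2, 8),
    "min_child_weight": (1, 10),
    "subsample": (0.2, 0.8),
    "colsample_bytree": (0.2, 0.9),
    "nrounds": (50, 5000),
}

INTEGER_PARAMS = frozenset({"max_depth", "min_child_weight", "nrounds"})

#: Published optima shipped as ready-to-use defaults for the two tasks.
CLASSIFICATION_OPTIMA = {
    "eta": 0.00107,
    "gamma": 0.137,
    "max_depth": 5,
    "min_child_weight": 9,
    "subsample": 0.207,
    "colsample_bytree": 0.793,
    "nrounds": 4328,
}
REGRESSION_OPTIMA = {
    "eta": 0.00889,
    "gamma": 2.08,
    "max_depth": 2,
    "min_child_weight": 8,
    "subsample": 0.783,
    "colsample_bytree": 0.672,
    "nrounds": 1810,
}

#: Covariates entering the classification design after feature selection
#: (self-reported alcohol is offered to the selector but was not retained).
DEFAULT_COVARIATES = ("age", "sex", "alcohol")


@dataclass
class HyperParams:
    eta: float
    gamma: float
    max_depth: int
    min_child_weight: int
    subsample: float
    colsample_bytree: float
    nrounds: int

    def validate(self, space: dict[str, tuple[float, float]] | None = None):
        space = space or DEFAULT_SEARCH_SPACE
        for name, (lo, hi) in space.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside declared range [{lo}, {hi}]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def classification_default(cls) -> "HyperParams":
        return cls(**CLASSIFICATION_OPTIMA)

    @classmethod
    def regression_default(cls) -> "HyperParams":
        return cls(**REGRESSION_OPTIMA)


@dataclass
class SplitPlan:
    train_ids: pd.Index
    test_ids: pd.Index
    frac: float
    seed: int

    def __post_init__(self):
        overlap = self.train_ids.intersection(self.test_ids)
        if len(overlap):
            raise ValueError("train and test ids overlap")


@dataclass
class LogoPartition:
    """One LOGOCV fold: training rows exclude the validation region."""

    region: object
    train_ids: pd.Index  # train-partition rows with region != this one
    holdout_ids: pd.Index  # train-partition rows of this region


@dataclass
class FeatureSelection:
    features: list[str]  # intersection, ordered by mean rank
    top_lists: dict  # region -> top-k ranked list
    importances: dict  # region -> pd.Series


@dataclass
class ModelBundle:
    """The per-region gradient-boosting models plus shared metadata."""

    task: str  # "classification" | "regression"
    variant: str  # "full" | "covariates-only" | "balances-only"
    feature_columns: list[str]
    params: HyperParams | dict
    models: dict = field(default_factory=dict)  # region -> fitted booster
    partitions: list[LogoPartition] = field(default_factory=list)
    per_model_features: dict | None = None  # region-independent variant
    per_model_params: dict | None = None
    seed: int = 0

    @property
    def regions(self) -> list:
        return list(self.models)

    def columns_for(self, region) -> list[str]:
        if self.per_model_features is not None:
            return self.per_model_features[region]
        return self.feature_columns

    def predict_scores(self, region, X: pd.DataFrame) -> np.ndarray:
        model = self.models[region]
        cols = self.columns_for(region)
        if self.task == "classification":
            return model.predict_proba(X[cols])[:, 1]
        return model.predict(X[cols])

    def save(self, directory) -> None:
        """Serialize as a directory: bundle.json plus one model file per
        region in the boosting library's native (JSON) format."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        params = self.params.to_dict() if isinstance(self.params, HyperParams) else self.params
        meta = {
            "task": self.task,
            "variant": self.variant,
            "feature_columns": self.feature_columns,
            "params": params,
            "seed": self.seed,
            "regions": [str(r) for r in self.models],
            "per_model_features": self.per_model_features,
            "per_model_params": {
                str(r): (p.to_dict() if isinstance(p, HyperParams) else p)
                for r, p in self.per_model_params.items()
            }
            if self.per_model_params
            else None,
            "provenance": {
                str(p.region): {
                    "n_train": len(p.train_ids),
                    "n_holdout": len(p.holdout_ids),
                }
                for p in self.partitions
            },
        }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))
        for r, model in self.models.items():
            # booster-level save: the native JSON format, independent of
            # the sklearn wrapper's mixin state
            model.get_booster().save_model(str(d / f"model_{r}.json"))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        bundle = cls(
            task=meta["task"],
            variant=meta["variant"],
            feature_columns=meta["feature_columns"],
            params=meta["params"],
            per_model_features=meta.get("per_model_features"),
            seed=meta.get("seed", 0),
        )
        maker = XGBClassifier if meta["task"] == "classification" else XGBRegressor
        for r in meta["regions"]:
            model = maker()
            model.load_model(str(d / f"model_{r}.json"))
            key = int(r) if r.lstrip("-").isdigit() else r
            bundle.models[key] = model
        if bundle.per_model_features is not None:
            bundle.per_model_features = {
                (int(k) if k.lstrip("-").isdigit() else k): v
                for k, v in bundle.per_model_features.items()
            }
        return bundle


@dataclass
class MetricsReport:
    task: str
    per_region: pd.DataFrame
    curves: dict = field(default_factory=dict)
    averaged: dict | None = None  # metrics of the mean-over-models prediction

    @property
    def mean_auc(self) -> float:
        return float(self.per_region["auc"].mean())

    @property
    def mean_auprc(self) -> float:
        return float(self.per_region["auprc"].mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.per_region["rmse"].mean())


# --------------------------------------------------------------------------
# design assembly and splits
# --------------------------------------------------------------------------


def assemble_features(
    balances: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Join balances with numeric covariates into one samples x features frame."""
    ids = balances.index.intersection(cohort.index)
    X = balances.loc[ids].copy()
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (cohort.loc[ids, "sex"] == "M").astype(float)
        else:
            X[cov] = cohort.loc[ids, cov].astype(float)
    return X


def stratified_split(
    cohort: pd.DataFrame, frac: float = 0.7, seed: int = 0
) -> SplitPlan:
    """70/30 split preserving sex x region balance.

    Within every sex x region stratum, round(frac * n) samples go to the
    training partition (always at least within one sample of the target
    fraction); allocation is deterministic under ``seed``.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for _, idx in sorted(
        cohort.groupby(["sex", "region"], observed=True).groups.items(),
        key=lambda kv: str(kv[0]),
    ):
        ids = np.asarray(idx)
        rng.shuffle(ids)
        n_train = int(np.floor(frac * len(ids) + 0.5))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitPlan(
        train_ids=pd.Index(train), test_ids=pd.Index(test), frac=frac, seed=seed
    )


def logocv_partitions(split: SplitPlan, cohort: pd.DataFrame) -> list[LogoPartition]:
    """One partition per region; its rows never train their own model."""
    region = cohort.loc[split.train_ids, "region"]
    regions = sorted(cohort["region"].unique(), key=str)
    if len(regions) < 2:
        raise ValueError("LOGOCV needs at least 2 regions")
    parts = []
    for r in regions:
        holdout = split.train_ids[region == r]
        train = split.train_ids[region != r]
        if len(holdout) == 0:
            raise ValueError(f"region {r!r} has no training samples")
        parts.append(LogoPartition(region=r, train_ids=train, holdout_ids=holdout))
    return parts


# --------------------------------------------------------------------------
# feature selection
# --------------------------------------------------------------------------


def _new_forest(task: str, n_trees: int, seed: int, max_features="sqrt"):
    cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
    return cls(
        n_estimators=n_trees,
        bootstrap=True,
        max_features=max_features,
        n_jobs=1,
        random_state=seed,
    )


def select_features(
    partitions: list[LogoPartition],
    X: pd.DataFrame,
    y: pd.Series,
    top_k: int = 50,
    n_trees: int = 500,
    n_repeats: int = 5,
    seed: int = 0,
    task: str = "classification",
) -> FeatureSelection:
    """Intersection of per-fold top-k features by OOB permutation importance.

    For each LOGOCV subset a random forest is fit on that subset's
    training rows and every feature is ranked by out-of-bag permutation
    importance (ties broken by name for determinism).  The returned set is
    the plain intersection of the per-fold top-k lists, ordered by mean
    rank across folds.  An empty intersection is returned (with the
    per-fold lists for inspection), not raised.
    """
    if not partitions:
        raise ValueError("need at least one LOGOCV partition")
    top_lists: dict = {}
    importances: dict = {}
    ranks: dict[str, list[int]] = {}
    for i, part in enumerate(partitions):
        forest = _new_forest(task, n_trees, seed + i)
        Xi = X.loc[part.train_ids]
        yi = y.loc[part.train_ids]
        forest.fit(Xi, yi)
        imp = oob_permutation_importance(forest, Xi, yi, n_repeats=n_repeats, seed=seed + i)
        ranked = rank_features(imp)
        top_lists[part.region] = ranked[:top_k]
        importances[part.region] = imp
        for pos, name in enumerate(ranked):
            ranks.setdefault(name, []).append(pos)
    common = set.intersection(*(set(v) for v in top_lists.values()))
    ordered = sorted(common, key=lambda f: (float(np.mean(ranks[f])), f))
    return FeatureSelection(features=ordered, top_lists=top_lists, importances=importances)


# --------------------------------------------------------------------------
# boosting
# --------------------------------------------------------------------------


def _booster(task: str, params: HyperParams | dict, seed: int):
    p = params.to_dict() if isinstance(params, HyperParams) else dict(params)
    kwargs = dict(
        n_estimators=int(p["nrounds"]),
        learning_rate=p["eta"],
        gamma=p["gamma"],
        max_depth=int(p["max_depth"]),
        min_child_weight=p["min_child_weight"],
        subsample=p["subsample"],
        colsample_bytree=p["colsample_bytree"],
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )
    if task == "classification":
        return XGBClassifier(eval_metric="logloss", **kwargs)
    return XGBRegressor(objective="reg:squarederror", **kwargs)


def _fold_metric(task: str, y_true, scores) -> float:
    """Value to minimize: -AUC for classification, RMSE for regression."""
    if task == "classification":
        return -roc_auc_score(y_true, scores)
    return float(np.sqrt(np.mean((np.asarray(y_true, float) - scores) ** 2)))


def optimize_hyperparams(
    partitions: list[LogoPartition],
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    space: dict[str, tuple[float, float]] | None = None,
    n_random: int = 30,
    n_iter: int = 100,
    seed: int = 0,
    task: str = "classification",
):
    """GP/EI search of the boosting hyperparameters over the LOGOCV folds.

    The objective is the mean validation metric across folds: each
    candidate is trained on every fold's training rows and scored on the
    fold's held-out region rows.  Returns (HyperParams, OptimizationResult).
    """
    if n_random < 1 or n_iter < 0:
        raise ValueError("optimization budget must be positive")
    space = dict(space or DEFAULT_SEARCH_SPACE)
    if not features:
        raise ValueError("empty feature list")

    folds = [
        (
            X.loc[p.train_ids, features],
            y.loc[p.train_ids],
            X.loc[p.holdout_ids, features],
            y.loc[p.holdout_ids],
        )
        for p in partitions
    ]

    def objective(params: dict) -> float:
        vals = []
        for Xtr, ytr, Xva, yva in folds:
            model = _booster(task, params, seed)
            model.fit(Xtr, ytr)
            if task == "classification":
                scores = model.predict_proba(Xva)[:, 1]
            else:
                scores = model.predict(Xva)
            vals.append(_fold_metric(task, yva, scores))
        return float(np.mean(vals))

    result = minimize_ei(
        objective,
        bounds=space,
        n_random=n_random,
        n_iter=n_iter,
        seed=seed,
        integer_params=INTEGER_PARAMS,
    )
    best = HyperParams(**result.best_params).validate(space)
    return best, result


def _variant_columns(
    features: list[str],
    variant: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> list[str]:
    if variant == "full":
        return list(features)
    if variant == "covariates-only":
        return [c for c in covariates]
    if variant == "balances-only":
        return [f for f in features if f not in set(covariates) | {"alcohol"}]
    raise ValueError(f"unknown variant {variant!r}")


def train_bundle(
    partitions: list[LogoPartition],
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    params: HyperParams | dict,
    task: str = "classification",
    variant: str = "full",
    seed: int = 0,
) -> ModelBundle:
    """Train one boosted-tree model per LOGOCV fold on the chosen columns."""
    cols = _variant_columns(features, variant)
    if not cols:
        raise ValueError(f"variant {variant!r} leaves no feature columns")
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"features absent from design matrix: {missing[:5]}")
    bundle = ModelBundle(
        task=task,
        variant=variant,
        feature_columns=cols,
        params=params,
        partitions=list(partitions),
        seed=seed,
    )
    for part in partitions:
        model = _booster(task, params, seed)
        model.fit(X.loc[part.train_ids, cols], y.loc[part.train_ids])
        bundle.models[part.region] = model
    return bundle


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


def _classification_metrics(y_true: np.ndarray, scores: np.ndarray) -> dict:
    return {
        "auc": roc_auc_score(y_true, scores),
        "auprc": average_precision_score(y_true, scores),
        "baseline": float(np.mean(y_true)),
        "n": int(len(y_true)),
    }


def _regression_metrics(y_true: np.ndarray, scores: np.ndarray) -> dict:
    resid = y_true - scores
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "r2": float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else np.nan,
        "n": int(len(y_true)),
    }


def evaluate_internal(
    bundle: ModelBundle,
    split: SplitPlan,
    X: pd.DataFrame,
    y: pd.Series,
    cohort: pd.DataFrame,
) -> MetricsReport:
    """Score each model only on its omitted region's rows in the test set."""
    import warnings as _warnings

    region = cohort.loc[split.test_ids, "region"]
    rows = []
    curves = {}
    for r in bundle.regions:
        ids = split.test_ids[region == r]
        if len(ids) == 0:
            _warnings.warn(f"region {r!r} absent from test set; model skipped")
            continue
        scores = bundle.predict_scores(r, X.loc[ids])
        yt = np.asarray(y.loc[ids], dtype=float)
        if bundle.task == "classification":
            m = _classification_metrics(yt, scores)
            fpr, tpr, _ = roc_curve(yt, scores)
            prec, rec, _ = precision_recall_curve(yt, scores)
            curves[r] = {"roc": (fpr, tpr), "pr": (rec, prec)}
        else:
            m = _regression_metrics(yt, scores)
        rows.append({"region": r, **m})
    return MetricsReport(
        task=bundle.task,
        per_region=pd.DataFrame(rows).set_index("region"),
        curves=curves,
    )


def region_independent_variant(
    split: SplitPlan,
    X: pd.DataFrame,
    y: pd.Series,
    cohort: pd.DataFrame,
    space: dict | None = None,
    top_k: int = 50,
    n_trees: int = 500,
    n_repeats: int = 5,
    n_random: int = 30,
    n_iter: int = 100,
    n_nested_splits: int = 6,
    seed: int = 0,
    task: str = "classification",
) -> tuple[ModelBundle, MetricsReport]:
    """Models whose selection and optimization never see their validation region.

    Per region r: feature selection runs LOGOCV over the remaining regions
    only, and hyperparameters are optimized on ``n_nested_splits``
    randomized 70/30 splits of the region-r-free training rows.  Each
    model therefore carries individual features and parameters.
    """
    region_train = cohort.loc[split.train_ids, "region"]
    regions = sorted(cohort["region"].unique(), key=str)
    per_feat: dict = {}
    per_par: dict = {}
    bundle = ModelBundle(
        task=task,
        variant="region-independent",
        feature_columns=[],
        params={},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    for r in regions:
        ids = split.train_ids[region_train != r]
        sub_cohort = cohort.loc[ids]
        # inner LOGOCV over the remaining regions for feature selection
        inner_parts = []
        for r2 in sorted(sub_cohort["region"].unique(), key=str):
            inner_parts.append(
                LogoPartition(
                    region=r2,
                    train_ids=ids[sub_cohort["region"] != r2],
                    holdout_ids=ids[sub_cohort["region"] == r2],
                )
            )
        sel = select_features(
            inner_parts, X, y, top_k=top_k, n_trees=n_trees,
            n_repeats=n_repeats, seed=seed, task=task,
        )
        feats = sel.features or rank_features(
            sum(sel.importances.values()) / len(sel.importances)
        )[:top_k]
        # nested randomized 70/30 splits for hyperparameter optimization
        nested = []
        for j in range(n_nested_splits):
            perm = rng.permutation(len(ids))
            cut = int(np.floor(0.7 * len(ids) + 0.5))
            nested.append(
                LogoPartition(
                    region=f"nested{j}",
                    train_ids=ids[perm[:cut]],
                    holdout_ids=ids[perm[cut:]],
                )
            )
        params, _ = optimize_hyperparams(
            nested, X, y, feats, space=space, n_random=n_random,
            n_iter=n_iter, seed=seed, task=task,
        )
        model = _booster(task, params, seed)
        model.fit(X.loc[ids, feats], y.loc[ids])
        bundle.models[r] = model
        bundle.partitions.append(
            LogoPartition(region=r, train_ids=ids, holdout_ids=split.train_ids[region_train == r])
        )
        per_feat[r] = feats
        per_par[r] = params
    bundle.per_model_features = per_feat
    bundle.per_model_params = per_par
    report = evaluate_internal(bundle, split, X, y, cohort)
    return bundle, report


def external_validate(
    bundle: ModelBundle,
    new_counts: pd.DataFrame,
    new_cohort: pd.DataFrame,
    tree,
    training_taxa: list[str],
    pseudocount: float = 1.0,
    y: pd.Series | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> MetricsReport:
    """Apply a fitted bundle to a new cohort through the training transform.

    The new count table is subset to the taxa that passed filtering in the
    training cohort; taxa unobserved in the new data enter at pseudocount
    1, so every training balance name is reproducible by construction.
    Reports per-model metrics (and per-omitted-region metrics when the new
    cohort carries matching region labels) plus the metrics of the
    six-model-averaged prediction.
    """
    counts = new_counts.reindex(training_taxa).fillna(0).astype(np.int64)
    bal = PhilrTransform(tree=tree, pseudocount=pseudocount).fit(counts.T).transform(counts.T)
    X = assemble_features(bal, new_cohort, covariates=covariates)
    needed = set()
    for r in bundle.regions:
        needed.update(bundle.columns_for(r))
    missing = sorted(needed - set(X.columns))
    if missing:
        raise ValueError(f"unresolvable feature name(s) in new data: {missing[:5]}")
    if y is None:
        res = compute_fli(new_cohort)
        y = (assign_groups(res, "60-split") == "high").astype(float)
    y = y.loc[X.index]
    yt = np.asarray(y, dtype=float)

    metrics_fn = (
        _classification_metrics if bundle.task == "classification" else _regression_metrics
    )
    # Region-wise scoring (matching evaluate_internal) when the new cohort
    # carries all the bundle's region labels; otherwise every model is
    # scored on the whole new cohort.
    regionwise = "region" in new_cohort.columns and set(bundle.regions) <= set(
        new_cohort["region"]
    )
    rows = []
    curves = {}
    score_mat = {}
    for r in bundle.regions:
        scores = bundle.predict_scores(r, X)
        score_mat[r] = scores
        if regionwise:
            mask = (new_cohort.loc[X.index, "region"] == r).to_numpy()
            if mask.sum() and len(np.unique(yt[mask])) > 1:
                rows.append({"region": r, **metrics_fn(yt[mask], scores[mask])})
        else:
            rows.append({"region": r, **metrics_fn(yt, scores)})
    avg_scores = np.mean(np.vstack(list(score_mat.values())), axis=0)
    averaged = metrics_fn(yt, avg_scores)
    if bundle.task == "classification":
        fpr, tpr, _ = roc_curve(yt, avg_scores)
        prec, rec, _ = precision_recall_curve(yt, avg_scores)
        curves["averaged"] = {"roc": (fpr, tpr), "pr": (rec, prec)}
    return MetricsReport(
        task=bundle.task,
        per_region=pd.DataFrame(rows).set_index("region"),
        curves=curves,
        averaged=averaged,
    )
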