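"""Model interpretation: partial dependence, relative effects, and the
liver-function-specific feature dissection.

Partial dependence of a feature at value v is the mean predicted positive-
class probability (or regression output) over the evaluation rows with
that feature clamped to v.  A feature's relative effect is the median over
the per-region models of PD(feature max) - PD(feature min), evaluated at
the feature's observed extremes per model.

The liver-specific dissection strata participants into 18 categories
(age <40 / 40-60 / >=60  x  sex F/M  x  BMI <25 / 25-30 / >=30), runs
LOGOCV random-forest regressors for GGT and triglycerides per category,
intersects the per-run top-k importance lists, and finally intersects the
union over categories with the FLI-classification feature set: features
predictive of both are called liver-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fli import drop_missing_liver_rows
from .importance import oob_permutation_importance, rank_features
from .ml import LogoPartition, ModelBundle, _new_forest

__all__ = [
    "EffectReport",
    "LiverFeatureReport",
    "partial_dependence",
    "relative_effects",
    "build_strata",
    "liver_specific_features",
]

AGE_BINS = (-np.inf, 40.0, 60.0, np.inf)
AGE_LABELS = ("<40", "40-60", ">=60")
BMI_BINS = (-np.inf, 25.0, 30.0, np.inf)
BMI_LABELS = ("<25", "25-30", ">=30")


@dataclass
class EffectReport:
    """Partial-dependence curves and per-feature relative effects."""

    curves: dict = field(default_factory=dict)  # feature -> region -> (grid, pd)
    pd_extremes: pd.DataFrame | None = None  # rows (feature, region): pd_min, pd_max
    relative_effects: pd.Series | None = None  # median over models of pd_max - pd_min
    ranking: list[str] = field(default_factory=list)


@dataclass
class LiverFeatureReport:
    per_stratum: dict  # stratum id -> {target: feature list}
    strata: pd.DataFrame  # stratum bookkeeping: bins, n, used/skipped
    union: list[str]
    liver_specific: list[str]  # union intersected with the FLI feature set


def _eval_rows(bundle: ModelBundle, X: pd.DataFrame, region) -> pd.DataFrame:
    for part in bundle.partitions:
        if part.region == region:
            return X.loc[X.index.intersection(part.train_ids)]
    return X


def _pd_at(bundle: ModelBundle, region, rows: pd.DataFrame, feature: str, v) -> float:
    mod = rows[bundle.columns_for(region)].copy()
    mod[feature] = v
    if bundle.task == "classification":
        return float(bundle.models[region].predict_proba(mod)[:, 1].mean())
    return float(bundle.models[region].predict(mod).mean())


def partial_dependence(
    bundle: ModelBundle,
    X: pd.DataFrame,
    feature: str,
    grid: np.ndarray | None = None,
    n_grid: int = 20,
) -> EffectReport:
    """PD curve of one feature for every per-region model.

    Default grid: the feature's observed quantiles plus its min/max
    (collapsing to the unique observed values for e.g. binary features).
    """
    report = EffectReport()
    curves: dict = {}
    for r in bundle.regions:
        if feature not in bundle.columns_for(r):
            raise ValueError(f"feature {feature!r} not in model for region {r!r}")
        rows = _eval_rows(bundle, X, r)
        vals = rows[feature].to_numpy(dtype=float)
        if grid is None:
            if vals.max() == vals.min():
                raise ValueError(f"feature {feature!r} is constant (zero-width grid)")
            uniq = np.unique(vals)
            if len(uniq) <= n_grid:
                g = uniq
            else:
                g = np.unique(
                    np.quantile(vals, np.linspace(0, 1, n_grid), method="linear")
                )
        else:
            g = np.asarray(grid, dtype=float)
        curves[r] = (g, np.array([_pd_at(bundle, r, rows, feature, v) for v in g]))
    report.curves[feature] = curves
    return report


def relative_effects(bundle: ModelBundle, X: pd.DataFrame) -> EffectReport:
    """Median across models of PD at each feature's max minus at its min.

    Both the signed medians and the raw per-model (pd_min, pd_max) pairs
    are reported; features are ranked by absolute relative effect.
    """
    features = sorted(
        {f for r in bundle.regions for f in bundle.columns_for(r)}
    )
    recs = []
    effects = {}
    for f in features:
        diffs = []
        for r in bundle.regions:
            if f not in bundle.columns_for(r):
                continue
            rows = _eval_rows(bundle, X, r)
            vals = rows[f].to_numpy(dtype=float)
            pd_min = _pd_at(bundle, r, rows, f, vals.min())
            pd_max = _pd_at(bundle, r, rows, f, vals.max())
            recs.append(
                {"feature": f, "region": r, "pd_min": pd_min, "pd_max": pd_max}
            )
            diffs.append(pd_max - pd_min)
        effects[f] = float(np.median(diffs))
    eff = pd.Series(effects, name="relative_effect")
    ranking = list(eff.reindex(eff.abs().sort_values(ascending=False).index).index)
    return EffectReport(
        pd_extremes=pd.DataFrame(recs).set_index(["feature", "region"]),
        relative_effects=eff,
        ranking=ranking,
    )


def build_strata(cohort: pd.DataFrame) -> pd.Series:
    """Assign each participant to one of the 18 age x sex x BMI strata.

    Bins are half-open: age 40 falls in "40-60", 60 in ">=60"; BMI 25 in
    "25-30", 30 in ">=30".  Returns a Series of "age|sex|bmi" stratum ids.
    """
    age = pd.cut(cohort["age"], AGE_BINS, labels=AGE_LABELS, right=False)
    bmi = pd.cut(cohort["bmi"], BMI_BINS, labels=BMI_LABELS, right=False)
    return (
        age.astype(str) + "|" + cohort["sex"].astype(str) + "|" + bmi.astype(str)
    ).rename("stratum")


def liver_specific_features(
    cohort: pd.DataFrame,
    balances: pd.DataFrame,
    fli_features: list[str],
    top_k: int = 50,
    seed: int = 0,
    targets: tuple[str, ...] = ("ggt", "triglycerides"),
    min_stratum: int = 50,
    n_trees: int = 500,
    n_repeats: int = 5,
) -> LiverFeatureReport:
    """Balances predictive of GGT/triglycerides within age-sex-BMI strata.

    Rows missing GGT, triglycerides or BMI are removed (never imputed).
    Within each usable stratum and per target, random-forest regressors
    run over the LOGOCV region folds; the per-category feature set is the
    intersection of the top-k OOB-importance lists across folds.  The
    union over categories is intersected with ``fli_features``.
    """
    cohort = drop_missing_liver_rows(cohort)
    ids = cohort.index.intersection(balances.index)
    cohort = cohort.loc[ids]
    X = balances.loc[ids]
    strata = build_strata(cohort)

    per_stratum: dict = {}
    union: set[str] = set()
    book = []
    from .importance import rank_features as _rank

    for sid in sorted(strata.unique()):
        members = strata.index[strata == sid]
        n = len(members)
        regions = sorted(cohort.loc[members, "region"].unique(), key=str)
        usable = n >= min_stratum and len(regions) >= 2
        book.append({"stratum": sid, "n": n, "used": usable})
        if not usable:
            import warnings

            warnings.warn(f"stratum {sid!r} skipped (n={n})")
            continue
        parts = [
            LogoPartition(
                region=r,
                train_ids=members[cohort.loc[members, "region"] != r],
                holdout_ids=members[cohort.loc[members, "region"] == r],
            )
            for r in regions
        ]
        per_stratum[sid] = {}
        for target in targets:
            y = cohort.loc[members, target].astype(float)
            tops = []
            for i, part in enumerate(parts):
                forest = _new_forest("regression", n_trees, seed + i)
                Xi = X.loc[part.train_ids]
                yi = y.loc[part.train_ids]
                forest.fit(Xi, yi)
                imp = oob_permutation_importance(
                    forest, Xi, yi, n_repeats=n_repeats, seed=seed + i
                )
                tops.append(set(_rank(imp)[:top_k]))
            feats = sorted(set.intersection(*tops)) if tops else []
            per_stratum[sid][target] = feats
            union |= set(feats)
    liver = sorted(union & set(fli_features))
    return LiverFeatureReport(
        per_stratum=per_stratum,
        strata=pd.DataFrame(book).set_index("stratum"),
        union=sorted(union),
        liver_specific=liver,
    )
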