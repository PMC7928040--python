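"""Out-of-bag permutation importance for random forests.

Importance of a feature is the drop in out-of-bag accuracy (classification)
or the rise in out-of-bag MSE (regression) when that feature's values are
permuted, computed per tree on the tree's own out-of-bag samples and
averaged over the forest — the classic randomForest "mean decrease in
accuracy" scheme.  scikit-learn exposes no OOB variant of permutation
importance, so the bootstrap sample of each tree is reconstructed here from
its ``random_state`` (the documented draw: ``RandomState(rs).randint(0, n,
n)``), which reproduces sklearn's ``oob_decision_function_`` exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["oob_permutation_importance", "rank_features"]


def _oob_indices(estimator, n_samples: int) -> np.ndarray:
    rs = np.random.RandomState(estimator.random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.nonzero(mask)[0]


def oob_permutation_importance(
    forest: RandomForestClassifier | RandomForestRegressor,
    X,
    y,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Per-feature OOB permutation importance of a fitted forest.

    Parameters
    ----------
    forest : fitted RandomForest{Classifier,Regressor}
        Must have been fit with ``bootstrap=True`` on exactly ``(X, y)``.
    X : pd.DataFrame or ndarray
        The training matrix the forest was fit on.
    y : array-like
        The training target.
    n_repeats : int
        Permutations per (tree, feature); drops are averaged.

    Returns
    -------
    pd.Series
        Importance per feature (accuracy drop, or MSE increase for
        regression), averaged over all trees; features a tree never splits
        on contribute zero for that tree.
    """
    if not getattr(forest, "bootstrap", True):
        raise ValueError("OOB importance requires bootstrap=True")
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    classification = isinstance(forest, RandomForestClassifier)
    ya = np.asarray(y) if classification else np.asarray(y, dtype=float)
    n, p = Xa.shape
    rng = np.random.default_rng(seed)
    total = np.zeros(p)
    for est in forest.estimators_:
        oob = _oob_indices(est, n)
        if len(oob) == 0:
            continue
        X_oob = Xa[oob]
        y_oob = ya[oob]
        pred = est.predict(X_oob)
        if classification:
            base = np.mean(pred == y_oob)
        else:
            base = -np.mean((pred - y_oob) ** 2)
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        for j in used:
            saved = X_oob[:, j].copy()
            drop = 0.0
            for _ in range(n_repeats):
                X_oob[:, j] = saved[rng.permutation(len(saved))]
                perm_pred = est.predict(X_oob)
                if classification:
                    score = np.mean(perm_pred == y_oob)
                else:
                    score = -np.mean((perm_pred - y_oob) ** 2)
                drop += base - score
            X_oob[:, j] = saved
            total[j] += drop / n_repeats
    imp = total / len(forest.estimators_)
    if columns is not None:
        return pd.Series(imp, index=columns, name="importance")
    return pd.Series(imp, name="importance")


def rank_features(importance: pd.Series) -> list[str]:
    """Feature names sorted by (importance desc, name asc) — a stable,
    deterministic ranking even under exact ties."""
    df = importance.rename("imp").to_frame()
    df["name"] = df.index
    df = df.sort_values(["imp", "name"], ascending=[False, True])
    return list(df.index)
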