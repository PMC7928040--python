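"""Alpha/beta diversity and the regression stages linking them to FLI.

Shannon diversity is computed in nats as the mean over random rarefactions
of the raw counts; group differences are modelled with a binomial GLM
(high-FLI group on diversity, adjusted for age, sex and alcohol).  Beta
diversity is the Euclidean geometry of the PhILR balances summarized by
unscaled PCA, and log10(FLI) is regressed on the first three PCs plus
covariates by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fli import FLIResult

__all__ = [
    "DiversityResult",
    "OrdinationResult",
    "ModelSummary",
    "shannon_rarefied",
    "diversity_group_model",
    "pca_balances",
    "fli_linear_model",
    "summarize_phylum",
]


@dataclass
class DiversityResult:
    shannon: pd.Series  # mean H (nats) per sample
    depth: int
    n_rarefactions: int


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x PCs
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    loadings: pd.DataFrame  # balances x PCs


@dataclass
class ModelSummary:
    """Coefficient table plus fit statistics of a regression stage."""

    coefficients: pd.DataFrame  # columns: coef, se, p
    n_used: int
    aic: float | None = None
    adj_r2: float | None = None
    warnings: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients.loc[name, "coef"])

    def pvalue(self, name: str) -> float:
        return float(self.coefficients.loc[name, "p"])


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def shannon_rarefied(
    table: pd.DataFrame,
    n_rarefactions: int = 10,
    depth: int | None = None,
    seed: int = 0,
) -> DiversityResult:
    """Mean Shannon diversity (nats) over random rarefactions per sample.

    Each rarefaction subsamples the sample's reads without replacement to
    ``depth`` (default: the minimum sample depth).  H is bounded above by
    ln(number of taxa).
    """
    totals = table.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    too_shallow = totals[totals < depth]
    if len(too_shallow):
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total count of sample(s) "
            f"{list(too_shallow.index[:5])}"
        )
    rng = np.random.default_rng(seed)
    counts = table.to_numpy(dtype=np.int64).T  # samples x taxa
    out = np.zeros(counts.shape[0])
    for i, row in enumerate(counts):
        acc = 0.0
        for _ in range(n_rarefactions):
            sub = rng.multivariate_hypergeometric(row, depth)
            acc += _shannon(sub.astype(float))
        out[i] = acc / n_rarefactions
    return DiversityResult(
        shannon=pd.Series(out, index=table.columns, name="shannon"),
        depth=depth,
        n_rarefactions=n_rarefactions,
    )


def _listwise(frames: dict[str, pd.Series]) -> pd.DataFrame:
    df = pd.DataFrame(frames)
    return df.dropna()


def diversity_group_model(
    div: DiversityResult, fli: FLIResult, cohort: pd.DataFrame
) -> ModelSummary:
    """Binomial GLM: high-FLI group ~ Shannon + age + sex + alcohol.

    Rows with missing values are listwise-deleted.  Complete separation is
    flagged in ``warnings`` rather than silently returned.
    """
    if fli.groups is None:
        raise ValueError("assign FLI groups before modelling")
    y = (fli.groups == "high").astype(float)
    y[fli.groups.isna() | (fli.groups == "excluded")] = np.nan
    df = _listwise(
        {
            "high": y,
            "shannon": div.shannon,
            "age": cohort["age"],
            "sex": (cohort["sex"] == "M").astype(float),
            "alcohol": cohort["alcohol"],
        }
    )
    X = sm.add_constant(df[["shannon", "age", "sex", "alcohol"]])
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.GLM(df["high"], X, family=sm.families.Binomial()).fit()
        for w in caught:
            if "separat" in str(w.message).lower():
                notes.append(f"possible separation: {w.message}")
    if np.abs(fit.params).max() > 50:
        notes.append("extreme coefficients; likely complete separation")
    coefs = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return ModelSummary(
        coefficients=coefs, n_used=len(df), aic=float(fit.aic), warnings=notes
    )


def pca_balances(balances: pd.DataFrame, k: int = 3) -> OrdinationResult:
    """Centered, unscaled PCA of a samples x balances matrix.

    Balances already share the log-ratio scale, so no per-column
    standardization is applied and sample-to-sample Euclidean distances
    are preserved across the rotation.
    """
    X = balances.to_numpy(dtype=float)
    n, p = X.shape
    if n < k + 1:
        raise ValueError("need at least k+1 samples for a k-axis ordination")
    rank = min(n - 1, p)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; returning {rank} axes")
        k = rank
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eig = s**2 / (n - 1)
    scores = U[:, :k] * s[:k]
    cols = [f"PC{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=balances.index, columns=cols),
        eigenvalues=eig[:k],
        proportion_variance=eig[:k] / eig.sum(),
        loadings=pd.DataFrame(Vt[:k].T, index=balances.columns, columns=cols),
    )


def fli_linear_model(
    fli: FLIResult, ordination: OrdinationResult, cohort: pd.DataFrame, n_pcs: int = 3
) -> ModelSummary:
    """OLS of log10(FLI) on the first PCs plus sex, age and alcohol."""
    pcs = ordination.scores.iloc[:, :n_pcs]
    # a zero-variance axis (degenerate ordination) carries no information;
    # drop it so the model nests down to the covariates-only fit
    pcs = pcs.loc[:, pcs.std() > 0]
    df = _listwise(
        {
            "log10_fli": np.log10(fli.fli),
            **{c: pcs[c] for c in pcs.columns},
            "sex": (cohort["sex"] == "M").astype(float),
            "age": cohort["age"],
            "alcohol": cohort["alcohol"],
        }
    )
    X = sm.add_constant(df.drop(columns="log10_fli"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(df["log10_fli"], X).fit()
    coefs = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return ModelSummary(
        coefficients=coefs, n_used=len(df), adj_r2=float(fit.rsquared_adj)
    )


def plot_fli_quantiles(
    ordination: OrdinationResult,
    fli: FLIResult,
    n_quantiles: int = 10,
    cutoff: float = 60.0,
):
    """FLI against quantile bins of the first PCs (exploratory figure).

    Returns a matplotlib Figure: one panel per PC axis, mean FLI per
    score quantile with the steatosis cutoff as a dashed line.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pcs = ordination.scores
    fig, axes = plt.subplots(1, pcs.shape[1], figsize=(4 * pcs.shape[1], 3.2),
                             squeeze=False)
    for ax, pc in zip(axes[0], pcs.columns):
        q = pd.qcut(pcs[pc], n_quantiles, labels=False, duplicates="drop")
        means = fli.fli.groupby(q).mean()
        ax.plot(means.index + 1, means.to_numpy(), marker="o")
        ax.axhline(cutoff, linestyle="--", color="grey")
        ax.set_xlabel(f"{pc} quantile")
        ax.set_ylabel("mean FLI")
    fig.tight_layout()
    return fig


def summarize_phylum(
    table: pd.DataFrame, taxonomy: dict[str, str], groups: pd.Series
) -> pd.DataFrame:
    """Mean relative abundance per phylum within each FLI group.

    Taxa missing from ``taxonomy`` map to ``"unclassified"``.  Rows are
    groups, columns phyla; each row sums to 1 by total-sum scaling.
    """
    phyla = pd.Series(
        [taxonomy.get(t, "unclassified") for t in table.index], index=table.index
    )
    merged = table.groupby(phyla).sum()  # phyla x samples
    rel = merged / merged.sum(axis=0)
    out = {}
    for label in groups.dropna().unique():
        ids = groups.index[groups == label].intersection(rel.columns)
        out[label] = rel[ids].mean(axis=1)
    return pd.DataFrame(out).T
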