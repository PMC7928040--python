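"""Fatty Liver Index (FLI) computation and group assignment.

The FLI of Bedogni et al. is a logistic-scale score built from four routine
measurements — serum triglycerides, BMI, gamma-glutamyl transferase (GGT) and
waist circumference — that estimates the likelihood of hepatic steatosis.
A score >= 60 rules steatosis in; < 30 rules it out.

The linear predictor is

    L = 0.953*ln(TG mg/dL) + 0.139*BMI + 0.718*ln(GGT U/L)
        + 0.053*waist_cm - 15.745

and FLI = 100 * e^L / (1 + e^L), so FLI lies strictly inside (0, 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FLI_COEF",
    "TG_MMOL_TO_MGDL",
    "FLIResult",
    "compute_fli",
    "assign_groups",
    "impute_for_ml",
    "drop_missing_liver_rows",
]

#: Published coefficients of the FLI linear predictor.
FLI_COEF = {
    "ln_triglycerides": 0.953,
    "bmi": 0.139,
    "ln_ggt": 0.718,
    "waist": 0.053,
    "intercept": -15.745,
}

#: Conversion factor for triglycerides, mmol/L -> mg/dL.  The FLI formula
#: requires mg/dL; this helper constant is provided for callers with SI-unit
#: data and is never applied silently.
TG_MMOL_TO_MGDL = 88.57

#: Columns the linear predictor needs.
FLI_COMPONENTS = ("triglycerides", "bmi", "ggt", "waist")


@dataclass
class FLIResult:
    """Per-sample FLI values and derived group labels.

    Attributes
    ----------
    linear_predictor : pd.Series
        The dimensionless score L (NaN where components were missing).
    fli : pd.Series
        100 * expit(L), strictly inside (0, 100) where defined.
    groups : pd.Series or None
        Labels from :func:`assign_groups`; None until groups are assigned.
    scheme : str or None
        The cutoff scheme used for ``groups``.
    imputed : pd.DataFrame
        Boolean flags marking imputed component cells (empty if none).
    """

    linear_predictor: pd.Series
    fli: pd.Series
    groups: pd.Series | None = None
    scheme: str | None = None
    imputed: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_missing(self) -> int:
        return int(self.fli.isna().sum())


def _linear_predictor(tg, bmi, ggt, waist):
    tg = np.asarray(tg, dtype=float)
    ggt = np.asarray(ggt, dtype=float)
    if np.any(tg[np.isfinite(tg)] <= 0) or np.any(ggt[np.isfinite(ggt)] <= 0):
        raise ValueError(
            "triglycerides and GGT must be positive (mg/dL and U/L); "
            "ln is undefined at or below zero"
        )
    return (
        FLI_COEF["ln_triglycerides"] * np.log(tg)
        + FLI_COEF["bmi"] * np.asarray(bmi, dtype=float)
        + FLI_COEF["ln_ggt"] * np.log(ggt)
        + FLI_COEF["waist"] * np.asarray(waist, dtype=float)
        + FLI_COEF["intercept"]
    )


def compute_fli(cohort: pd.DataFrame) -> FLIResult:
    """Compute the Fatty Liver Index for every row of a cohort table.

    Parameters
    ----------
    cohort : pd.DataFrame
        Must contain ``triglycerides`` (mg/dL), ``bmi`` (kg/m^2), ``ggt``
        (U/L) and ``waist`` (cm).  Rows with a missing component get NaN
        FLI and are reported through :attr:`FLIResult.n_missing` rather
        than raising.

    Returns
    -------
    FLIResult
    """
    missing_cols = [c for c in FLI_COMPONENTS if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort table lacks FLI components: {missing_cols}")
    L = pd.Series(
        _linear_predictor(
            cohort["triglycerides"], cohort["bmi"], cohort["ggt"], cohort["waist"]
        ),
        index=cohort.index,
        name="linear_predictor",
    )
    # 100 * expit(L): numerically stable in both tails.
    from scipy.special import expit

    fli = pd.Series(100.0 * expit(L), index=cohort.index, name="fli")
    return FLIResult(linear_predictor=L, fli=fli)


def assign_groups(result: FLIResult, scheme: str = "60-split") -> pd.Series:
    """Assign FLI group labels under one of the two cutoff schemes.

    ``"60-split"``: low (FLI < 60) vs high (FLI >= 60) — the main analysis
    contrast.  ``"30/60-split"``: low (FLI < 30) vs high (FLI >= 60), with
    intermediate participants (30 <= FLI < 60) labelled ``excluded``.

    The result is stored on ``result.groups`` and also returned.
    """
    if scheme not in ("60-split", "30/60-split"):
        raise ValueError(f"unknown scheme {scheme!r}; use '60-split' or '30/60-split'")
    fli = result.fli
    labels = pd.Series(pd.NA, index=fli.index, dtype="object", name="fli_group")
    if scheme == "60-split":
        labels[fli < 60] = "low"
        labels[fli >= 60] = "high"
    else:
        labels[fli < 30] = "low"
        labels[(fli >= 30) & (fli < 60)] = "excluded"
        labels[fli >= 60] = "high"
    result.groups = labels
    result.scheme = scheme
    return labels


def impute_for_ml(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = ("fli", "alcohol"),
    means: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-impute FLI and self-reported alcohol for the ML pipeline.

    Parameters
    ----------
    cohort : pd.DataFrame
    columns : tuple of str
        Columns to mean-impute (default: FLI and alcohol, the two the
        modelling stage fills in).
    means : pd.Series, optional
        Pre-computed column means (e.g. from the training partition, to
        avoid leaking test-set information).  Defaults to the means of the
        provided table.

    Returns
    -------
    (imputed table, boolean flag frame marking filled cells)

    Raises
    ------
    ValueError
        If a requested column is entirely missing (no mean to impute with).
    """
    out = cohort.copy()
    flags = pd.DataFrame(False, index=cohort.index, columns=list(columns))
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in cohort table")
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot mean-impute")
        mean = float(means[col]) if means is not None else float(vals.mean())
        mask = vals.isna()
        out.loc[mask, col] = mean
        flags[col] = mask.to_numpy()
    return out, flags


def drop_missing_liver_rows(
    cohort: pd.DataFrame, columns: tuple[str, ...] = ("ggt", "triglycerides", "bmi")
) -> pd.DataFrame:
    """Listwise-delete rows missing GGT, triglycerides or BMI.

    Used by the liver-function-specific feature dissection, which never
    imputes these measurements.
    """
    present = [c for c in columns if c in cohort.columns]
    return cohort.dropna(subset=present)
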