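"""Dirichlet Monte-Carlo differential abundance between FLI groups.

Per Monte-Carlo instance, each sample's composition is drawn from
Dirichlet(counts + prior) and CLR-transformed; a Welch's t-test compares
the two groups per taxon, and Benjamini-Hochberg correction is applied
across taxa within the instance.  Reported per taxon are the mean t
statistic, the expected (mean) BH-adjusted p-value (Q) over instances, and
an effect size: the median over instances of the between-group difference
in median CLR abundance.  This mirrors the ALDEx2 procedure of the
compositional data-analysis literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DiffAbundResult", "diff_abundance"]


@dataclass
class DiffAbundResult:
    """Per-taxon differential-abundance summary.

    ``table`` columns: ``t`` (mean Welch t), ``q`` (expected BH-adjusted
    p), ``effect`` (median between-group CLR difference; positive means
    higher in the high/positive group), ``direction``.
    """

    table: pd.DataFrame
    q_threshold: float = 0.001

    def significant(self, q_threshold: float | None = None) -> pd.DataFrame:
        q = self.q_threshold if q_threshold is None else q_threshold
        return self.table[self.table["q"] < q]

    def positive(self) -> pd.DataFrame:
        sig = self.significant()
        return sig[sig["effect"] > 0].sort_values("effect", key=np.abs, ascending=False)

    def negative(self) -> pd.DataFrame:
        sig = self.significant()
        return sig[sig["effect"] < 0].sort_values("effect", key=np.abs, ascending=False)


def _bh(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def diff_abundance(
    table: pd.DataFrame,
    groups: pd.Series,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    positive_label=None,
) -> DiffAbundResult:
    """ALDEx2-style Welch's t differential abundance.

    Parameters
    ----------
    table : pd.DataFrame
        Taxa x samples integer counts.
    groups : pd.Series
        Binary labels indexed by sample id; samples with other/NA labels
        are ignored.  ``positive_label`` names the group whose enrichment
        yields a positive effect (default: "high" if present, else the
        lexicographically larger label).
    n_mc : int
        Number of Dirichlet Monte-Carlo instances (>= 2).
    prior : float
        Dirichlet prior added to every count.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    groups = groups.dropna()
    labels = sorted(map(str, groups.unique()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if positive_label is None:
        positive_label = "high" if "high" in labels else labels[-1]
    positive_label = str(positive_label)
    if positive_label not in labels:
        raise ValueError(f"positive_label {positive_label!r} not among {labels}")
    negative_label = next(l for l in labels if l != positive_label)

    ids = groups.index.intersection(table.columns)
    groups = groups.loc[ids]
    pos_ids = groups.index[groups.astype(str) == positive_label]
    neg_ids = groups.index[groups.astype(str) == negative_label]
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValueError("each group needs at least 2 samples")

    rng = np.random.default_rng(seed)
    counts = table[list(pos_ids) + list(neg_ids)].to_numpy(dtype=float).T
    n_pos = len(pos_ids)
    alpha = counts + prior

    n_taxa = counts.shape[1]
    t_sum = np.zeros(n_taxa)
    q_sum = np.zeros(n_taxa)
    effects = np.empty((n_mc, n_taxa))
    for m in range(n_mc):
        gam = rng.standard_gamma(alpha)
        comp = gam / gam.sum(axis=1, keepdims=True)
        logc = np.log(comp)
        clr = logc - logc.mean(axis=1, keepdims=True)
        a, b = clr[:n_pos], clr[n_pos:]
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        t_sum += t
        q_sum += _bh(p)
        effects[m] = np.median(a, axis=0) - np.median(b, axis=0)

    out = pd.DataFrame(
        {
            "t": t_sum / n_mc,
            "q": q_sum / n_mc,
            "effect": np.median(effects, axis=0),
        },
        index=table.index,
    )
    out["direction"] = np.where(
        out["effect"] > 0, f"higher in {positive_label}", f"higher in {negative_label}"
    )
    return DiffAbundResult(table=out)
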