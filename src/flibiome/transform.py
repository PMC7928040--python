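"""Taxon/sample filtering and compositional transforms (PhILR balances, CLR).

Count tables are pandas DataFrames with taxa as rows and samples as columns
(the conventional orientation of metagenomic feature tables).  Balance
matrices are samples x balances, one balance per internal node of a rooted
binary phylogeny.

The phylogenetic isometric log-ratio (PhILR) balance at internal node k,
whose two child clades have leaf sets R (numerator, first child) and S
(denominator, second child), is

    b_k = sqrt(r*s / (r+s)) * ln( g(x_R) / g(x_S) )

with r = |R|, s = |S| and g the geometric mean of the (pseudocounted,
closed) relative abundances.  The collection of all such balances is an
orthonormal log-ratio basis: Euclidean distance between balance vectors
equals the Aitchison (CLR-Euclidean) distance between the compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FilterSpec",
    "BalanceMatrix",
    "filter_taxa",
    "filter_samples",
    "PhilrTransform",
    "philr_transform",
    "clr_transform",
    "name_internal_nodes",
]


@dataclass
class FilterSpec:
    """Thresholds for taxon and sample filtering.

    Taxa are retained when seen with more than ``min_count`` reads in at
    least ``min_prevalence`` of samples AND their coefficient of variation
    across all samples exceeds ``cv_threshold``.  Samples are removed when
    their read depth is below ``min_reads_per_sample`` or when flagged
    pregnant / on antibiotics within 6 months.
    """

    min_count: int = 3
    min_prevalence: float = 0.01
    cv_threshold: float = 3.0
    cv_keep_above: bool = True  # retain CV > threshold; set False to invert
    min_reads_per_sample: int = 50_000
    exclude_pregnant: bool = True
    exclude_antibiotics: bool = True

    def __post_init__(self):
        if self.min_count < 0 or self.cv_threshold < 0 or self.min_reads_per_sample < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ValueError("min_prevalence must lie in [0, 1]")


@dataclass
class BalanceMatrix:
    """Samples x balances matrix plus the sequential binary partition.

    Attributes
    ----------
    values : pd.DataFrame
        Samples (rows) by named balances (columns).
    partition : dict
        balance id -> (numerator leaf tuple, denominator leaf tuple).
    """

    values: pd.DataFrame
    partition: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    @property
    def balance_ids(self) -> list[str]:
        return list(self.values.columns)

    def clade_sizes(self, balance_id: str) -> tuple[int, int]:
        num, den = self.partition[balance_id]
        return len(num), len(den)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def sidecar(self) -> dict:
        return {
            b: {"numerator": list(num), "denominator": list(den)}
            for b, (num, den) in self.partition.items()
        }


def filter_taxa(
    table: pd.DataFrame, spec: FilterSpec | None = None, return_report: bool = False
):
    """Apply the prevalence and coefficient-of-variation taxon filters.

    A taxon passes when (a) it has more than ``spec.min_count`` reads in at
    least ``spec.min_prevalence`` of the samples and (b) its coefficient of
    variation (SD/mean over all samples) is above ``spec.cv_threshold``.
    Both the threshold and the direction of the CV rule are configurable
    (``cv_keep_above=False`` keeps low-CV taxa instead).

    Returns the filtered table; with ``return_report=True`` also a
    DataFrame stating why each removed taxon failed.
    """
    if spec is None:
        spec = FilterSpec()
    if table.empty:
        raise ValueError("empty abundance table")
    counts = table.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    prevalence = (counts > spec.min_count).sum(axis=1) / n_samples
    mean = counts.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, counts.std(axis=1, ddof=1) / mean, 0.0)
    pass_prev = prevalence >= spec.min_prevalence
    pass_cv = cv > spec.cv_threshold if spec.cv_keep_above else cv <= spec.cv_threshold
    keep = pass_prev & pass_cv
    if not keep.any():
        raise ValueError(
            "taxon filtering removed every taxon; relax FilterSpec thresholds"
        )
    out = table.loc[keep]
    if return_report:
        report = pd.DataFrame(
            {
                "prevalence": prevalence,
                "cv": cv,
                "fails_prevalence": ~pass_prev,
                "fails_cv": ~pass_cv,
            },
            index=table.index,
        ).loc[~keep]
        return out, report
    return out


def filter_samples(
    table: pd.DataFrame, cohort: pd.DataFrame, spec: FilterSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-depth, pregnant, or antibiotic-exposed samples.

    Depth is taken from a ``read_depth`` cohort column when present,
    otherwise from the table's column sums.  The strict rule is "fewer
    than ``min_reads_per_sample`` reads are removed" (a sample at exactly
    the threshold is kept).
    """
    if spec is None:
        spec = FilterSpec()
    shared = table.columns.intersection(cohort.index)
    if len(shared) == 0:
        raise ValueError("abundance table and cohort table share no sample ids")
    table = table[shared]
    cohort = cohort.loc[shared]
    if "read_depth" in cohort.columns:
        depth = cohort["read_depth"].to_numpy(dtype=float)
    else:
        depth = table.sum(axis=0).to_numpy(dtype=float)
    keep = depth >= spec.min_reads_per_sample
    if spec.exclude_pregnant and "pregnant" in cohort.columns:
        keep &= ~cohort["pregnant"].fillna(False).astype(bool).to_numpy()
    if spec.exclude_antibiotics and "antibiotics_6mo" in cohort.columns:
        keep &= ~cohort["antibiotics_6mo"].fillna(False).astype(bool).to_numpy()
    kept_ids = shared[keep]
    return table[kept_ids], cohort.loc[kept_ids]


def name_internal_nodes(tree: TreeNode, prefix: str = "n") -> TreeNode:
    """Assign deterministic preorder names n1, n2, ... to unnamed internal nodes."""
    k = 0
    for node in tree.preorder():
        if not node.is_tip():
            k += 1
            if not node.name:
                node.name = f"{prefix}{k}"
    return tree


def _check_binary(tree: TreeNode) -> None:
    bad = [
        node.name or "<unnamed>"
        for node in tree.preorder()
        if not node.is_tip() and len(node.children) != 2
    ]
    if bad:
        raise ValueError(
            "tree is not strictly binary at internal node(s) "
            f"{bad[:5]}; resolve multifurcations before the balance transform"
        )


def _node_bookkeeping(tree: TreeNode):
    """Preorder list of (name, numerator leaves, denominator leaves)."""
    out = []
    for node in tree.preorder():
        if node.is_tip():
            continue
        first, second = node.children
        num = tuple(t.name for t in first.tips()) or (first.name,)
        den = tuple(t.name for t in second.tips()) or (second.name,)
        out.append((node.name, num, den))
    return out


class PhilrTransform(TransformerMixin, BaseEstimator):
    """Phylogenetic ILR (balance) transform as a scikit-learn transformer.

    Parameters
    ----------
    tree : skbio.TreeNode or str
        Rooted binary phylogeny over (a superset of) the table's taxa; a
        Newick string is also accepted.  The tree is pruned to the taxa
        observed in the fitted table.
    pseudocount : float, default 1.0
        Added before closure; by default only to zero counts ("a
        pseudocount of 1 for taxa absent in an individual sample").
    zeros_only : bool, default True
        If False the pseudocount is added to every cell.

    The transformer consumes samples x taxa frames (sklearn orientation).
    Fitted attributes: ``taxa_``, ``balance_names_``, ``partition_``,
    ``tree_`` (the pruned, named working tree).
    """

    def __init__(self, tree=None, pseudocount: float = 1.0, zeros_only: bool = True):
        self.tree = tree
        self.pseudocount = pseudocount
        self.zeros_only = zeros_only

    def fit(self, X: pd.DataFrame, y=None):
        if self.tree is None:
            raise ValueError("PhilrTransform requires a tree")
        tree = self.tree
        if isinstance(tree, str):
            tree = TreeNode.read(StringIO(tree))
        taxa = list(X.columns)
        tip_names = {t.name for t in tree.tips()}
        missing = [t for t in taxa if t not in tip_names]
        if missing:
            raise ValueError(
                f"{len(missing)} taxa absent from the tree, e.g. {missing[:5]}"
            )
        work = tree.copy()
        if set(taxa) != tip_names:
            work = work.shear(taxa)
            work.prune()
        name_internal_nodes(work)
        _check_binary(work)
        self.tree_ = work
        self.taxa_ = [t.name for t in work.tips()]
        nodes = _node_bookkeeping(work)
        self.balance_names_ = [n for n, _, _ in nodes]
        self.partition_ = {n: (num, den) for n, num, den in nodes}
        # Precompute index arrays and scale factors for fast transform.
        col = {t: i for i, t in enumerate(self.taxa_)}
        self._num_idx = [np.array([col[t] for t in num]) for _, num, _ in nodes]
        self._den_idx = [np.array([col[t] for t in den]) for _, _, den in nodes]
        self._scale = np.array(
            [
                np.sqrt(len(num) * len(den) / (len(num) + len(den)))
                for _, num, den in nodes
            ]
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "taxa_"):
            raise RuntimeError("PhilrTransform is not fitted")
        missing = [t for t in self.taxa_ if t not in X.columns]
        if missing:
            raise ValueError(f"taxa missing from input table: {missing[:5]}")
        mat = X[self.taxa_].to_numpy(dtype=float)
        if self.zeros_only:
            mat = np.where(mat == 0, self.pseudocount, mat)
        else:
            mat = mat + self.pseudocount
        if np.any(mat <= 0):
            raise ValueError("non-positive abundances after pseudocount")
        # closure then log; closure only shifts all logs by a per-sample
        # constant which cancels in every balance, but is kept for clarity
        props = mat / mat.sum(axis=1, keepdims=True)
        logp = np.log(props)
        n_bal = len(self.balance_names_)
        out = np.empty((mat.shape[0], n_bal))
        for j in range(n_bal):
            gm_num = logp[:, self._num_idx[j]].mean(axis=1)
            gm_den = logp[:, self._den_idx[j]].mean(axis=1)
            out[:, j] = self._scale[j] * (gm_num - gm_den)
        return pd.DataFrame(out, index=X.index, columns=self.balance_names_)


def philr_transform(
    table: pd.DataFrame, tree, pseudocount: float = 1.0, zeros_only: bool = True
) -> BalanceMatrix:
    """Transform a taxa x samples count table into phylogenetic balances.

    Thin functional wrapper over :class:`PhilrTransform` (which uses the
    sklearn samples x features orientation).
    """
    X = table.T
    est = PhilrTransform(tree=tree, pseudocount=pseudocount, zeros_only=zeros_only)
    values = est.fit(X).transform(X)
    return BalanceMatrix(values=values, partition=est.partition_)


def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a taxa x samples count table.

    Returns a samples x taxa frame: ln(x + pc) minus the per-sample mean of
    ln(x + pc).  Rows therefore sum to zero.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    mat = table.to_numpy(dtype=float).T + pseudocount
    if np.any(mat <= 0):
        raise ValueError(
            "non-positive values after pseudocount; CLR requires strictly "
            "positive abundances"
        )
    logm = np.log(mat)
    clr = logm - logm.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.columns, columns=table.index)
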