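"""Synthetic cohort generator with planted microbiome-liver associations.

Emulates the structure of a Finnish population-survey cohort: six
geographic regions, covariates driving a Fatty Liver Index (FLI) with
roughly 30% of participants above the FLI >= 60 steatosis cutoff, and a
species-level shotgun count table over a random rooted binary phylogeny.

A single standard-normal latent "liver score" z ties everything together:

* it loads on the four FLI components (ln triglycerides, BMI, ln GGT,
  waist), so FLI correlates with z;
* age and sex contribute to z, so the covariates are genuinely predictive;
* for each planted clade, leaves under the node's first child are shifted
  by +effect*z on the log-abundance scale and leaves under the second
  child by -effect*z, so exactly that node's balance carries signal.

Counts are Dirichlet-multinomial at a lognormal per-sample read depth
(overdispersion typical of metagenomes).  Everything is reproducible from
the config seed, and the component means are calibrated analytically (not
by trial) so that P(FLI >= 60) matches the configured target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from skbio import TreeNode

from .fli import FLI_COEF
from .transform import name_internal_nodes

__all__ = [
    "CovariateParams",
    "SimConfig",
    "generate_tree",
    "generate_cohort",
    "pick_planted_nodes",
]


@dataclass
class CovariateParams:
    """Distribution parameters for the simulated covariates.

    Means, latent-score loadings and residual SDs for the four FLI
    components; age is a truncated normal (years) and sex a fair coin.
    ``w_age``/``w_sex`` are the loadings of standardized age and sex
    (coded -1/+1, male positive) inside the latent liver score.
    """

    age_mean: float = 50.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (25.0, 74.0)
    w_age: float = 0.30
    w_sex: float = 0.30
    ln_tg_mean: float = 4.70  # ln(mg/dL), median ~110 mg/dL
    ln_tg_load: float = 0.35
    ln_tg_sd: float = 0.28
    bmi_mean: float = 26.0  # kg/m^2
    bmi_load: float = 3.2
    bmi_sd: float = 2.4
    ln_ggt_mean: float = 3.40  # ln(U/L), median ~30 U/L
    ln_ggt_load: float = 0.50
    ln_ggt_sd: float = 0.40
    waist_mean: float = 90.0  # cm
    waist_load: float = 7.0
    waist_sd: float = 6.0
    alcohol_ln_mean: float = 3.4  # ln(g ethanol / week) among drinkers
    alcohol_ln_sd: float = 1.0
    alcohol_zero_frac: float = 0.25
    pregnancy_rate: float = 0.03  # among women under 45
    antibiotics_rate: float = 0.05

    def __post_init__(self):
        for name in ("age_sd", "ln_tg_sd", "bmi_sd", "ln_ggt_sd", "waist_sd",
                     "alcohol_ln_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimConfig:
    """Full configuration of a synthetic cohort draw."""

    n_taxa: int = 64
    n_samples: int = 500
    n_regions: int = 6
    region_weights: tuple[float, ...] | None = None  # uniform when None
    high_fli_target_prevalence: float = 0.30
    planted_clades: list[tuple[str, float]] = field(default_factory=list)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    latent_noise_sd: float | None = None  # default: residual to unit variance
    taxa_logmean_sd: float = 2.0
    region_effect_sd: float = 0.15
    dm_concentration: float = 200.0
    depth_ln_mean: float = np.log(1e5)
    depth_ln_sd: float = 0.35
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if not 0.0 < self.high_fli_target_prevalence < 1.0:
            raise ValueError("high_fli_target_prevalence must lie in (0, 1)")
        if self.region_weights is not None:
            w = np.asarray(self.region_weights, dtype=float)
            if len(w) != self.n_regions or not np.isclose(w.sum(), 1.0):
                raise ValueError("region_weights must sum to 1 over n_regions")
        for _, eff in self.planted_clades:
            if not np.isfinite(eff):
                raise ValueError("planted effect sizes must be finite")


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted binary tree by coalescent-style pairwise joins.

    Leaves are named ``t0001 .. t<n>``; internal nodes ``n1 ..`` by
    deterministic preorder index.  Same (n_taxa, seed) always yields the
    identical Newick string.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_taxa)))
    lineages = [TreeNode(name=f"t{i + 1:0{width}d}") for i in range(n_taxa)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        parent = TreeNode(children=[left, right])
        lineages.append(parent)
    tree = lineages[0]
    for node in tree.traverse():
        node.length = 1.0
    return name_internal_nodes(tree)


def pick_planted_nodes(
    tree: TreeNode,
    n: int,
    seed: int,
    min_leaves: int = 2,
    max_leaves: int = 8,
) -> list[str]:
    """Deterministically choose ``n`` disjoint internal nodes to plant on.

    Candidates are non-root internal nodes whose clade holds between
    ``min_leaves`` and ``max_leaves`` leaves; nodes are drawn in shuffled
    order, skipping any whose leaf set overlaps an already-chosen clade.
    """
    rng = np.random.default_rng(seed)
    candidates = [
        (node.name, frozenset(t.name for t in node.tips()))
        for node in tree.preorder()
        if not node.is_tip() and node.parent is not None
    ]
    candidates = [
        (name, leaves)
        for name, leaves in candidates
        if min_leaves <= len(leaves) <= max_leaves
    ]
    order = rng.permutation(len(candidates))
    chosen: list[str] = []
    used: set[str] = set()
    for k in order:
        name, leaves = candidates[k]
        if leaves & used:
            continue
        chosen.append(name)
        used |= leaves
        if len(chosen) == n:
            return chosen
    raise ValueError(
        f"could only place {len(chosen)} of {n} disjoint planted clades; "
        "grow the tree or widen the clade-size range"
    )


def _truncnorm_moments(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    d = stats.truncnorm(a, b, loc=mean, scale=sd)
    return d.mean(), d.std()


def _calibrated_waist_mean(cfg: SimConfig) -> float:
    """Waist mean shifted so that P(FLI >= 60) hits the target prevalence.

    The linear predictor L is (approximately) Gaussian under the
    generative model; its mean and SD follow from the component loadings,
    so the required location shift is available in closed form and is
    applied to the waist mean.
    """
    p = cfg.covariate_params
    c = FLI_COEF
    mu_L = (
        c["ln_triglycerides"] * p.ln_tg_mean
        + c["bmi"] * p.bmi_mean
        + c["ln_ggt"] * p.ln_ggt_mean
        + c["waist"] * p.waist_mean
        + c["intercept"]
    )
    lam = (
        c["ln_triglycerides"] * p.ln_tg_load
        + c["bmi"] * p.bmi_load
        + c["ln_ggt"] * p.ln_ggt_load
        + c["waist"] * p.waist_load
    )
    resid = np.sqrt(
        (c["ln_triglycerides"] * p.ln_tg_sd) ** 2
        + (c["bmi"] * p.bmi_sd) ** 2
        + (c["ln_ggt"] * p.ln_ggt_sd) ** 2
        + (c["waist"] * p.waist_sd) ** 2
    )
    sd_L = np.sqrt(lam**2 + resid**2)
    cut = logit(0.60)  # FLI >= 60 <=> L >= logit(0.6)
    target_mu = cut - sd_L * stats.norm.ppf(1 - cfg.high_fli_target_prevalence)
    return p.waist_mean + (target_mu - mu_L) / c["waist"]


def generate_cohort(config: SimConfig, tree: TreeNode | None = None):
    """Draw a full synthetic cohort.

    Returns
    -------
    (counts, cohort, tree, truth)
        ``counts``: taxa x samples integer DataFrame; ``cohort``: per-sample
        covariate DataFrame; ``tree``: the phylogeny used; ``truth``: dict
        with planted node ids/effects/leaf sets and the latent liver score.
    """
    rng = np.random.default_rng(config.seed)
    p = config.covariate_params
    n = config.n_samples

    if tree is None:
        tree = generate_tree(config.n_taxa, seed=config.seed)
    taxa = [t.name for t in tree.tips()]
    if len(taxa) != config.n_taxa:
        raise ValueError("provided tree does not have n_taxa leaves")
    node_leaves = {
        node.name: (
            tuple(t.name for t in node.children[0].tips()) or (node.children[0].name,),
            tuple(t.name for t in node.children[1].tips()) or (node.children[1].name,),
        )
        for node in tree.preorder()
        if not node.is_tip()
    }
    for node_id, _ in config.planted_clades:
        if node_id not in node_leaves:
            raise ValueError(f"planted node {node_id!r} is not an internal tree node")

    sample_ids = [f"s{i + 1:05d}" for i in range(n)]

    # --- covariates ------------------------------------------------------
    lo, hi = p.age_range
    a, b = (lo - p.age_mean) / p.age_sd, (hi - p.age_mean) / p.age_sd
    age = stats.truncnorm(a, b, loc=p.age_mean, scale=p.age_sd).rvs(n, random_state=rng)
    age_m, age_s = _truncnorm_moments(p.age_mean, p.age_sd, lo, hi)
    male = rng.random(n) < 0.5
    sexc = np.where(male, 1.0, -1.0)

    noise_sd = config.latent_noise_sd
    if noise_sd is None:
        resid_var = 1.0 - p.w_age**2 - p.w_sex**2
        if resid_var <= 0:
            raise ValueError("w_age^2 + w_sex^2 must be < 1 for a unit-variance score")
        noise_sd = float(np.sqrt(resid_var))
    z = p.w_age * (age - age_m) / age_s + p.w_sex * sexc + noise_sd * rng.standard_normal(n)

    waist_mean = _calibrated_waist_mean(config)
    ln_tg = p.ln_tg_mean + p.ln_tg_load * z + p.ln_tg_sd * rng.standard_normal(n)
    bmi = p.bmi_mean + p.bmi_load * z + p.bmi_sd * rng.standard_normal(n)
    ln_ggt = p.ln_ggt_mean + p.ln_ggt_load * z + p.ln_ggt_sd * rng.standard_normal(n)
    waist = waist_mean + p.waist_load * z + p.waist_sd * rng.standard_normal(n)
    bmi = np.maximum(bmi, 15.0)
    waist = np.maximum(waist, 55.0)

    alcohol = np.exp(p.alcohol_ln_mean + p.alcohol_ln_sd * rng.standard_normal(n))
    alcohol[rng.random(n) < p.alcohol_zero_frac] = 0.0
    pregnant = (~male) & (age < 45) & (rng.random(n) < p.pregnancy_rate)
    antibiotics = rng.random(n) < p.antibiotics_rate

    if config.region_weights is None:
        weights = np.full(config.n_regions, 1.0 / config.n_regions)
    else:
        weights = np.asarray(config.region_weights, dtype=float)
    region = rng.choice(np.arange(1, config.n_regions + 1), size=n, p=weights)

    depth = np.exp(
        config.depth_ln_mean + config.depth_ln_sd * rng.standard_normal(n)
    ).astype(np.int64)

    # --- microbiome ------------------------------------------------------
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    alpha = config.taxa_logmean_sd * rng.standard_normal(config.n_taxa)
    region_shift = config.region_effect_sd * rng.standard_normal(
        (config.n_regions, config.n_taxa)
    )
    loglam = alpha[None, :] + region_shift[region - 1]
    for node_id, eff in config.planted_clades:
        num, den = node_leaves[node_id]
        loglam[:, [taxon_idx[t] for t in num]] += eff * z[:, None]
        loglam[:, [taxon_idx[t] for t in den]] -= eff * z[:, None]
    theta = np.exp(loglam - loglam.max(axis=1, keepdims=True))
    theta /= theta.sum(axis=1, keepdims=True)
    # Dirichlet-multinomial via per-sample gamma draws
    gam = rng.standard_gamma(config.dm_concentration * theta)
    probs = gam / gam.sum(axis=1, keepdims=True)
    counts = np.empty((n, config.n_taxa), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depth[i], probs[i])

    cohort = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male, "M", "F"),
            "region": region,
            "triglycerides": np.exp(ln_tg),
            "ggt": np.exp(ln_ggt),
            "bmi": bmi,
            "waist": waist,
            "alcohol": alcohol,
            "pregnant": pregnant,
            "antibiotics_6mo": antibiotics,
            "read_depth": depth,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if config.missing_rate > 0:
        for col in ("triglycerides", "ggt", "bmi", "waist", "alcohol"):
            mask = rng.random(n) < config.missing_rate
            cohort.loc[mask, col] = np.nan

    counts_df = pd.DataFrame(
        counts.T, index=pd.Index(taxa, name="taxon"), columns=cohort.index
    )
    truth = {
        "planted_clades": [
            {
                "node": node_id,
                "effect": float(eff),
                "numerator": list(node_leaves[node_id][0]),
                "denominator": list(node_leaves[node_id][1]),
            }
            for node_id, eff in config.planted_clades
        ],
        "latent_score": dict(zip(sample_ids, z.tolist())),
        "calibrated_waist_mean": float(waist_mean),
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("covariate_params", "planted_clades")
            },
            "covariate_params": asdict(p),
            "planted_clades": [[nid, float(e)] for nid, e in config.planted_clades],
        },
    }
    return counts_df, cohort, tree, truth
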