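"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import flibiome as fb


def bruteforce_balances(counts: pd.DataFrame, tree, pseudocount=1.0) -> pd.DataFrame:
    """Independent evaluation of the balance formula by explicit clade
    enumeration: recursively collect each internal node's two descendant
    leaf sets and apply sqrt(r*s/(r+s)) * ln(g_R / g_S) directly."""
    mat = counts.T.to_numpy(dtype=float)
    mat = np.where(mat == 0, pseudocount, mat)
    props = mat / mat.sum(axis=1, keepdims=True)
    col = {t: i for i, t in enumerate(counts.index)}

    def leaves(node):
        if node.is_tip():
            return [node.name]
        out = []
        for child in node.children:
            out.extend(leaves(child))
        return out

    rows = {}
    for node in tree.preorder():
        if node.is_tip():
            continue
        R = leaves(node.children[0])
        S = leaves(node.children[1])
        r, s = len(R), len(S)
        gR = np.exp(np.mean(np.log(props[:, [col[t] for t in R]]), axis=1))
        gS = np.exp(np.mean(np.log(props[:, [col[t] for t in S]]), axis=1))
        rows[node.name] = math.sqrt(r * s / (r + s)) * np.log(gR / gS)
    return pd.DataFrame(rows, index=counts.columns)


def fli_by_hand(tg, bmi, ggt, waist):
    """The printed closed form, written out independently."""
    L = (
        0.953 * math.log(tg)
        + 0.139 * bmi
        + 0.718 * math.log(ggt)
        + 0.053 * waist
        - 15.745
    )
    return 100.0 * math.exp(L) / (1.0 + math.exp(L))


@pytest.fixture(scope="session")
def planted_sim():
    """A moderate planted cohort shared by the ML and interpretation tests.

    40 taxa, 600 samples, 6 regions, three planted clades with a strong
    effect — big enough for the boosting/selection machinery to behave,
    small enough to build once per session.
    """
    tree = fb.generate_tree(40, seed=2)
    nodes = fb.pick_planted_nodes(tree, 3, seed=2)
    cfg = fb.SimConfig(
        n_taxa=40,
        n_samples=600,
        seed=11,
        planted_clades=[(nd, 0.9) for nd in nodes],
    )
    counts, cohort, tree, truth = fb.generate_cohort(cfg, tree=tree)
    res = fb.compute_fli(cohort)
    groups = fb.assign_groups(res)
    bal = fb.philr_transform(counts, tree)
    X = fb.assemble_features(bal.values, cohort)
    y = (groups == "high").astype(float)
    split = fb.stratified_split(cohort, 0.7, seed=1)
    parts = fb.logocv_partitions(split, cohort)
    return {
        "tree": tree,
        "nodes": nodes,
        "counts": counts,
        "cohort": cohort,
        "truth": truth,
        "balances": bal,
        "X": X,
        "y": y,
        "fli": res,
        "groups": groups,
        "split": split,
        "partitions": parts,
    }


@pytest.fixture(scope="session")
def small_bundle(planted_sim):
    """A trained classification bundle on the shared planted cohort."""
    sim = planted_sim
    sel = fb.select_features(
        sim["partitions"], sim["X"], sim["y"], top_k=15, n_trees=50,
        n_repeats=2, seed=1,
    )
    params = fb.HyperParams(
        eta=0.1, gamma=0.5, max_depth=4, min_child_weight=2,
        subsample=0.7, colsample_bytree=0.8, nrounds=150,
    )
    features = sel.features or list(sim["X"].columns[:10])
    bundle = fb.train_bundle(
        sim["partitions"], sim["X"], sim["y"], features, params, seed=1
    )
    return {"bundle": bundle, "selection": sel, "params": params}
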