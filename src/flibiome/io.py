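"""Plain-text IO for the pipeline's tables and trees.

Count tables travel as TSV (taxa rows, samples columns), cohort tables as
CSV indexed by sample id, trees as Newick, and balance sidecars / truth
records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

__all__ = [
    "read_counts",
    "write_counts",
    "read_cohort",
    "write_cohort",
    "read_tree",
    "write_tree",
    "read_json",
    "write_json",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "taxon"
    return df.astype("int64")


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    for col in ("pregnant", "antibiotics_6mo"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path)


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path))


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
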