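"""Condition- and cluster-labeled cell cohorts, and their count/proportion tables.

A cohort is a plain :class:`pandas.DataFrame` with columns ``cell_id``,
``condition`` and ``cluster`` — one row per cell.  Every cell carries two
labels: the experimental group it came from and the cluster it was assigned
to by an upstream clustering step (labels are consumed as given; no
clustering happens here).  All downstream statistics are built from the
clusters × conditions count table derived from such a cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("cell_id", "condition", "cluster")


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell annotation table and return it unchanged.

    Raises
    ------
    ValueError
        If the table is empty ("no cells"), a required column is missing,
        a ``cell_id`` is duplicated, or any label is empty/missing.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table is missing column(s): {', '.join(missing)}")
    if len(annotations) == 0:
        raise ValueError("no cells: annotation table is empty")
    if annotations["cell_id"].duplicated().any():
        dupes = annotations.loc[annotations["cell_id"].duplicated(), "cell_id"].unique()
        raise ValueError(f"duplicate cell_id(s): {', '.join(map(str, dupes[:5]))}")
    for col in ("condition", "cluster"):
        vals = annotations[col]
        if vals.isna().any() or (vals.astype(str).str.len() == 0).any():
            raise ValueError(f"empty or missing {col} label(s) in annotation table")
    return annotations


def build_count_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Tally cells into a clusters × conditions count table.

    Rows are cluster labels, columns are condition labels, both in
    lexicographic order (fixed at construction so every downstream vector
    aligns deterministically).  Clusters absent from a condition appear as
    explicit zeros.
    """
    validate_annotations(annotations)
    table = pd.crosstab(annotations["cluster"], annotations["condition"])
    table = table.sort_index(axis=0).sort_index(axis=1)
    table.index.name = "cluster"
    table.columns.name = "condition"
    return table.astype(np.int64)


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a count table to per-condition proportions (columns sum to 1)."""
    totals = counts.sum(axis=0)
    empty = totals.index[totals == 0]
    if len(empty):
        raise ValueError(
            f"condition(s) with zero cells cannot be converted to proportions: "
            f"{', '.join(map(str, empty))}"
        )
    return counts / totals


def delta_proportions(
    proportions: pd.DataFrame, cond1: str, cond2: str
) -> pd.Series:
    """Per-cluster proportion difference Δp_j = p_1j − p_2j between two conditions."""
    for cond in (cond1, cond2):
        if cond not in proportions.columns:
            raise ValueError(f"unknown condition label: {cond!r}")
    delta = proportions[cond1] - proportions[cond2]
    delta.name = "delta_p"
    return delta


def cluster_order(annotations: pd.DataFrame) -> list:
    """Deterministic (lexicographic) cluster ordering used by all tables."""
    return sorted(annotations["cluster"].unique())


def condition_sizes(annotations: pd.DataFrame, conditions: Sequence[str]) -> pd.Series:
    """Number of annotated cells per requested condition."""
    counts = annotations["condition"].value_counts()
    for cond in conditions:
        if cond not in counts.index:
            raise ValueError(f"unknown condition label: {cond!r}")
    return counts.loc[list(conditions)]
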