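"""Differential Proportion Analysis (DPA).

A permutation test for whether a cluster's share of cells differs between
two conditions more than expected under partial random relabeling.  The
statistic is the observed proportion difference Δp_j = p_1j − p_2j.  The
null distribution is built by repeatedly relabeling a fraction ``w`` of all
cells: ``round(w·n)`` cells are selected uniformly at random and their
cluster labels are replaced by a sub-sample (without replacement) of the
pooled label multiset of all ``n`` cells; condition labels never move.
Two-tailed empirical p-values are

    P_increase = (1/t) Σ_i I(Δp_i ≥ Δp_j)
    P_decrease = (1/t) Σ_i I(Δp_i ≤ Δp_j)

with ties counted in both tails, and the reported P_j is their minimum.

Because the unrelabeled ``(1−w)·n`` cells retain the observed difference,
the null is centered near ``(1−w)·Δp_j`` rather than 0; smaller ``w``
therefore makes the test *stricter* (an observed difference has to stand
far above the relabeling noise to look extreme against its own null).

Reproducibility contract
------------------------
All randomness flows from one seeded :class:`numpy.random.Generator`.  Each
permutation consumes exactly two draws, in this order:

1. ``rng.choice(n, size=k, replace=False)`` — indices of the cells to relabel;
2. ``rng.choice(n, size=k, replace=False)`` — indices of the cells whose
   labels are donated (a without-replacement sub-sample of the pooled
   multiset).

An independent implementation making the same two calls per permutation
reproduces the null matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    build_count_table,
    delta_proportions,
    to_proportions,
    validate_annotations,
)

__all__ = ["DpaConfig", "DpaResult", "permute_labels", "dpa_null", "dpa_test"]


@dataclass(frozen=True)
class DpaConfig:
    """Parameters of the DPA permutation test.

    w
        Fraction of cells relabeled per permutation, in [0, 1].  Default 0.1.
    t
        Number of permutations (≥ 1).
    seed
        Seed for the random generator.
    report_floor
        When True, p-values of exactly 0 are displayed as ``<1/t`` in
        formatted output (the numeric value stays 0; the empirical formula
        permits it).
    """

    w: float = 0.1
    t: int = 1000
    seed: int | None = None
    report_floor: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t}")


@dataclass
class DpaResult:
    """Per-cluster DPA output plus the configuration that produced it."""

    table: pd.DataFrame
    cond1: str
    cond2: str
    config: DpaConfig = field(repr=False)

    def formatted(self) -> pd.DataFrame:
        """Copy of the result table with zero p-values floored to ``<1/t``."""
        out = self.table.copy()
        if self.config.report_floor:
            floor = f"<{1.0 / self.config.t:g}"
            for col in ("p_increase", "p_decrease", "p_final"):
                out[col] = out[col].map(lambda p: floor if p == 0.0 else f"{p:.17g}")
        return out


def _n_relabeled(w: float, n: int) -> int:
    # Round half to even (numpy/python default); the convention is fixed and
    # documented because w*n is frequently a half-integer.
    return int(round(w * n))


def permute_labels(
    annotations: pd.DataFrame, w: float, rng: np.random.Generator
) -> pd.DataFrame:
    """One partial relabeling of a cohort (cluster labels only).

    Exactly ``round(w·n)`` cells receive labels drawn without replacement
    from the pooled label multiset of all cells; a selected cell may receive
    its own label back.  Condition labels and row order are untouched.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must be in [0, 1], got {w}")
    validate_annotations(annotations)
    n = len(annotations)
    k = _n_relabeled(w, n)
    out = annotations.copy()
    if k == 0:
        return out
    labels = annotations["cluster"].to_numpy()
    sel = rng.choice(n, size=k, replace=False)
    donors = rng.choice(n, size=k, replace=False)
    new_labels = labels.copy()
    new_labels[sel] = labels[donors]
    out["cluster"] = new_labels
    return out


def _encode(annotations: pd.DataFrame, cond1: str, cond2: str):
    """Integer-code labels for the fast permutation loop."""
    validate_annotations(annotations)
    clusters = sorted(annotations["cluster"].unique())
    cluster_codes = pd.Categorical(
        annotations["cluster"], categories=clusters
    ).codes.astype(np.int64)
    cond = annotations["condition"].to_numpy()
    mask1 = cond == cond1
    mask2 = cond == cond2
    for name, mask in ((cond1, mask1), (cond2, mask2)):
        if not mask.any():
            raise ValueError(f"unknown condition label: {name!r}")
    return clusters, cluster_codes, mask1, mask2


def dpa_null(
    annotations: pd.DataFrame,
    cond1: str,
    cond2: str,
    config: DpaConfig,
) -> np.ndarray:
    """The t × J null matrix of Δp vectors from relabeled cohorts.

    Row i holds Δp for every cluster (lexicographic order) recomputed from
    the i-th relabeled cohort.  Bitwise reproducible for a fixed seed.
    """
    clusters, codes, mask1, mask2 = _encode(annotations, cond1, cond2)
    J = len(clusters)
    n = len(codes)
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    k = _n_relabeled(config.w, n)
    rng = np.random.default_rng(config.seed)

    idx1 = np.flatnonzero(mask1)
    idx2 = np.flatnonzero(mask2)
    null = np.empty((config.t, J), dtype=np.float64)
    for i in range(config.t):
        lab = codes
        if k > 0:
            sel = rng.choice(n, size=k, replace=False)
            donors = rng.choice(n, size=k, replace=False)
            lab = codes.copy()
            lab[sel] = codes[donors]
        p1 = np.bincount(lab[idx1], minlength=J) / n1
        p2 = np.bincount(lab[idx2], minlength=J) / n2
        null[i] = p1 - p2
    return null


def dpa_test(
    annotations: pd.DataFrame,
    cond1: str,
    cond2: str,
    config: DpaConfig,
) -> DpaResult:
    """Run DPA between two conditions of a cohort.

    Returns a :class:`DpaResult` whose table (indexed by cluster, in
    lexicographic order) carries the observed counts, proportions, Δp and
    the empirical p-values ``p_increase``, ``p_decrease`` and
    ``p_final = min(p_increase, p_decrease)``.
    """
    counts = build_count_table(annotations)
    props = to_proportions(counts)
    observed = delta_proportions(props, cond1, cond2)

    null = dpa_null(annotations, cond1, cond2, config)
    obs = observed.to_numpy()
    p_inc = (null >= obs).mean(axis=0)
    p_dec = (null <= obs).mean(axis=0)

    table = pd.DataFrame(
        {
            "n_cond1": counts[cond1],
            "n_cond2": counts[cond2],
            "p_cond1": props[cond1],
            "p_cond2": props[cond2],
            "delta_p": observed,
            "p_increase": p_inc,
            "p_decrease": p_dec,
            "p_final": np.minimum(p_inc, p_dec),
        }
    )
    table.index.name = "cluster"
    return DpaResult(table=table, cond1=cond1, cond2=cond2, config=config)
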