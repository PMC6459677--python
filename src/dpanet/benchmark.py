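"""Simulation benchmarks comparing DPA against per-cluster Fisher's exact tests.

Two designs:

* **replicate** — two replicate experiments of one biological system (10
  populations by default) whose true proportions are identical up to a
  noise perturbation; every significance call is a false positive.
* **condition** — a control vs condition experiment in which six of ten
  populations truly change (multiplicative factors applied before
  renormalization) and four stay the same, so sensitivity, specificity and
  precision are all defined.

Noise is injected by multiplying each population proportion independently
by (1 ± e) with equal probability and renormalizing; cells are then drawn
multinomially.  Ground truth is defined at the level of generative intent:
a population counts as "changed" only if its pre-normalization proportion
was deliberately multiplied (renormalization moves the untouched ones
slightly; they remain negatives).

The default change factors are sized by power analysis so that every
changed population is detectable by the more conservative of the two
methods (DPA at w = 0.1 needs roughly |Δp| > 1.64·√(2/w)·σ ≈ 7.3σ) with a
≥ 5σ margin at the harshest noise level — large multiplicative shifts of
rare populations and strong depletions of mid-sized ones, the regime of
dramatic compositional change the test is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .annotations import build_count_table
from .dpa import DpaConfig, dpa_test

__all__ = [
    "ReplicateSimConfig",
    "ConditionSimConfig",
    "perturb_proportions",
    "simulate_replicate_pair",
    "simulate_control_condition",
    "fisher_per_cluster",
    "benchmark_metrics",
    "run_benchmark",
    "DEFAULT_BASE_PROPORTIONS",
    "DEFAULT_CHANGED_INDICES",
    "DEFAULT_CHANGE_FACTORS",
]

#: Ten populations spanning abundant to rare.
DEFAULT_BASE_PROPORTIONS = (0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.05, 0.03, 0.02, 0.01)

#: The six populations that truly change in the condition design (0-based).
DEFAULT_CHANGED_INDICES = (2, 4, 5, 7, 8, 9)

#: Multiplicative factors for the changed populations: strong depletion of
#: mid-sized populations and strong expansion of rare ones.
DEFAULT_CHANGE_FACTORS = (0.25, 0.1, 0.1, 5.0, 6.0, 8.0)


@dataclass(frozen=True)
class ReplicateSimConfig:
    """Replicate design: same true composition in both experiments."""

    base_proportions: tuple = DEFAULT_BASE_PROPORTIONS
    error_rate: float = 0.0
    n1: int = 5000
    n2: int = 3000
    reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("base_proportions must sum to 1")
        if self.error_rate < 0:
            raise ValueError("error_rate must be >= 0")


@dataclass(frozen=True)
class ConditionSimConfig:
    """Control vs condition design with a known changed/unchanged split."""

    base_proportions: tuple = DEFAULT_BASE_PROPORTIONS
    changed_indices: tuple = DEFAULT_CHANGED_INDICES
    change_factors: tuple = DEFAULT_CHANGE_FACTORS
    error_rate: float = 0.0
    n1: int = 4000  # control
    n2: int = 6000  # condition
    reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("base_proportions must sum to 1")
        if len(self.changed_indices) != len(self.change_factors):
            raise ValueError("changed_indices and change_factors must align")
        if any(f <= 0 for f in self.change_factors):
            raise ValueError("change factors must be > 0")
        if self.error_rate < 0:
            raise ValueError("error_rate must be >= 0")

    @property
    def truth_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.base_proportions), dtype=bool)
        mask[list(self.changed_indices)] = True
        return mask

    def condition_proportions(self) -> np.ndarray:
        """Base proportions with change factors applied, renormalized."""
        p = np.asarray(self.base_proportions, dtype=float).copy()
        for i, f in zip(self.changed_indices, self.change_factors):
            p[i] *= f
        return p / p.sum()


def perturb_proportions(
    p: np.ndarray, e: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply each proportion independently by (1 ± e), then renormalize."""
    p = np.asarray(p, dtype=float)
    if e < 0:
        raise ValueError("error rate must be >= 0")
    if e >= 1:
        raise ValueError("error rate must be < 1 (proportions must stay positive)")
    if e == 0:
        return p.copy()
    signs = rng.choice([-1.0, 1.0], size=p.shape)
    out = p * (1.0 + signs * e)
    return out / out.sum()


def _cohort_frame(
    counts1: np.ndarray, counts2: np.ndarray, cond_names: tuple[str, str]
) -> pd.DataFrame:
    J = len(counts1)
    labels = [f"P{j:02d}" for j in range(J)]
    clusters = np.concatenate(
        [
            np.repeat(labels, counts1),
            np.repeat(labels, counts2),
        ]
    )
    conditions = np.concatenate(
        [
            np.repeat(cond_names[0], counts1.sum()),
            np.repeat(cond_names[1], counts2.sum()),
        ]
    )
    n = len(clusters)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "condition": conditions,
            "cluster": clusters,
        }
    )


def simulate_replicate_pair(
    config: ReplicateSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one replicate-design cohort (conditions ``rep1`` / ``rep2``).

    Each arm is a multinomial draw from an independently perturbed copy of
    the base proportions; ground truth: no population changed.
    """
    base = np.asarray(config.base_proportions, dtype=float)
    p1 = perturb_proportions(base, config.error_rate, rng)
    p2 = perturb_proportions(base, config.error_rate, rng)
    c1 = rng.multinomial(config.n1, p1)
    c2 = rng.multinomial(config.n2, p2)
    return _cohort_frame(c1, c2, ("rep1", "rep2"))


def simulate_control_condition(
    config: ConditionSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw one control-vs-condition cohort plus its truth mask.

    Change factors are applied to the condition arm before the error-rate
    perturbation (noise acts on the already-shifted composition).
    """
    base = np.asarray(config.base_proportions, dtype=float)
    cond = config.condition_proportions()
    p1 = perturb_proportions(base, config.error_rate, rng)
    p2 = perturb_proportions(cond, config.error_rate, rng)
    c1 = rng.multinomial(config.n1, p1)
    c2 = rng.multinomial(config.n2, p2)
    return _cohort_frame(c1, c2, ("control", "condition")), config.truth_mask


def fisher_per_cluster(
    counts: pd.DataFrame, cond1: str, cond2: str
) -> pd.Series:
    """Two-sided Fisher's exact p per cluster on its 2×2 membership table."""
    for cond in (cond1, cond2):
        if cond not in counts.columns:
            raise ValueError(f"unknown condition label: {cond!r}")
    n1 = int(counts[cond1].sum())
    n2 = int(counts[cond2].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot run Fisher's exact test on an empty condition")
    pvals = {}
    for cluster, row in counts.iterrows():
        a, b = int(row[cond1]), int(row[cond2])
        _, p = fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")
        pvals[cluster] = p
    out = pd.Series(pvals, name="p_fisher")
    out.index.name = "cluster"
    return out


def benchmark_metrics(
    calls: np.ndarray, truth: np.ndarray
) -> tuple[float, float, float]:
    """(sensitivity, specificity, precision) of boolean calls against truth.

    Undefined ratios default to the vacuous value 1.0 (no positives to find,
    or no positive calls made).
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    return sensitivity, specificity, precision


@dataclass
class _Accumulator:
    sensitivity: list = field(default_factory=list)
    specificity: list = field(default_factory=list)
    precision: list = field(default_factory=list)

    def add(self, metrics: tuple[float, float, float]) -> None:
        s, sp, pr = metrics
        self.sensitivity.append(s)
        self.specificity.append(sp)
        self.precision.append(pr)


def run_benchmark(
    design: str,
    error_rates: Sequence[float] = (0.01, 0.05, 0.1, 0.15, 0.2),
    reps: int = 100,
    dpa_config: DpaConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    base_proportions: Sequence[float] = DEFAULT_BASE_PROPORTIONS,
    n1: int | None = None,
    n2: int | None = None,
    change_factors: Sequence[float] = DEFAULT_CHANGE_FACTORS,
    changed_indices: Sequence[int] = DEFAULT_CHANGED_INDICES,
) -> pd.DataFrame:
    """Run one benchmark design over a grid of error rates.

    For each repetition a fresh cohort is simulated, both DPA (with a child
    seed derived from the master seed) and per-cluster Fisher tests are run,
    calls are made at ``alpha`` on raw p-values, and metrics are averaged
    over repetitions.  Returns a tidy frame with columns ``design``,
    ``error_rate``, ``method``, ``sensitivity``, ``specificity``,
    ``precision`` (sensitivity is NaN for the replicate design, which has no
    true positives).
    """
    if design not in ("replicate", "condition"):
        raise ValueError(f"design must be 'replicate' or 'condition', got {design!r}")
    if dpa_config is None:
        dpa_config = DpaConfig(w=0.1, t=1000)
    rng = np.random.default_rng(seed)

    if design == "replicate":
        conds = ("rep1", "rep2")
        n1 = 5000 if n1 is None else n1
        n2 = 3000 if n2 is None else n2
    else:
        conds = ("control", "condition")
        n1 = 4000 if n1 is None else n1
        n2 = 6000 if n2 is None else n2

    rows = []
    for e in error_rates:
        acc = {"DPA": _Accumulator(), "Fisher": _Accumulator()}
        for _ in range(reps):
            if design == "replicate":
                cfg = ReplicateSimConfig(
                    base_proportions=tuple(base_proportions),
                    error_rate=e,
                    n1=n1,
                    n2=n2,
                )
                cohort = simulate_replicate_pair(cfg, rng)
                truth = np.zeros(len(base_proportions), dtype=bool)
            else:
                cfg = ConditionSimConfig(
                    base_proportions=tuple(base_proportions),
                    changed_indices=tuple(changed_indices),
                    change_factors=tuple(change_factors),
                    error_rate=e,
                    n1=n1,
                    n2=n2,
                )
                cohort, truth = simulate_control_condition(cfg, rng)

            child_seed = int(rng.integers(2**31))
            cfg_dpa = DpaConfig(
                w=dpa_config.w, t=dpa_config.t, seed=child_seed,
                report_floor=dpa_config.report_floor,
            )
            dpa_res = dpa_test(cohort, conds[0], conds[1], cfg_dpa)
            p_dpa = dpa_res.table["p_final"].to_numpy()
            counts = build_count_table(cohort)
            p_fis = fisher_per_cluster(counts, conds[0], conds[1]).to_numpy()

            # Cohorts can (very rarely, for rare populations) drop a cluster
            # entirely; cluster labels are lexicographic P00..P09, so the
            # table rows align with the truth mask by construction.
            present = np.array(
                [f"P{j:02d}" in dpa_res.table.index for j in range(len(truth))]
            )
            full_dpa = np.ones(len(truth))
            full_fis = np.ones(len(truth))
            full_dpa[present] = p_dpa
            full_fis[present] = p_fis

            acc["DPA"].add(benchmark_metrics(full_dpa < alpha, truth))
            acc["Fisher"].add(benchmark_metrics(full_fis < alpha, truth))
        for method, a in acc.items():
            rows.append(
                {
                    "design": design,
                    "error_rate": e,
                    "method": method,
                    "sensitivity": (
                        float(np.mean(a.sensitivity)) if design == "condition" else np.nan
                    ),
                    "specificity": float(np.mean(a.specificity)),
                    "precision": float(np.mean(a.precision)),
                }
            )
    return pd.DataFrame(rows)
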