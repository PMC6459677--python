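"""Weighted four-layer ligand-receptor communication networks.

The network has four layers of nodes: source populations → ligands →
receptors → target populations.  Edge weights are, in order, the log2
fold-change of the ligand in the source population (vs all remaining
cells), a protein-association confidence in [0, 1] carried by the
ligand-receptor map, and the log2 fold-change of the receptor in the
target.  A *path weight* is the raw, unnormalized sum of the three weights,
so expression contributes the dominant share.

Pipeline per ordered (source, target) population pair:

1. enumerate candidate paths — every map pair whose ligand is detected in
   ≥ ``min_detection`` of source cells and whose receptor is detected in
   ≥ ``min_detection`` of target cells (T = number of such paths);
2. drop paths below ``min_path_weight`` (filters out down-regulated
   connections) and sum the survivors into w_st;
3. compare w_st against a randomized-network null: keep the pair's T
   ligand-receptor (PPI) weights, but draw T source→ligand and T
   receptor→target fold-changes at random (with replacement) from the
   pools of all detected ligand-side / receptor-side fold-changes across
   populations, re-filter and re-sum, m times.  The empirical p-value is
   P_w = (1/m) Σ I(w_i ≥ w_st), ties counted.
4. Benjamini-Hochberg correction across all pairs with T > 0, significance
   at adjusted p < alpha.

Reproducibility contract: each pair's null uses its own generator spawned
from the configured seed in the deterministic (sorted source, target)
order; within a pair, ligand indices are drawn first as an (m, T) block,
then receptor indices, in row chunks of ``chunk`` permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import (
    ExpressionMatrix,
    PopulationProfile,
    normalize_cptt_log,
    population_profiles,
)
from .io import atomic_write

__all__ = [
    "LrnetConfig",
    "validate_lr_map",
    "enumerate_candidate_paths",
    "filter_paths",
    "summed_weight",
    "permutation_pvalue",
    "bh_adjust",
    "lrnet_test",
    "lrnet_test_from_profile",
    "shuffle_fold_changes",
    "export_network",
]

logger = logging.getLogger(__name__)

PATH_COLUMNS = [
    "source",
    "ligand",
    "receptor",
    "target",
    "w_source_ligand",
    "w_lr",
    "w_receptor_target",
    "path_weight",
]
EDGE_COLUMNS = ["source", "target", "T", "n_filtered", "w_st", "p_w", "p_adj", "significant"]


@dataclass(frozen=True)
class LrnetConfig:
    """Parameters of the communication-network test.

    min_detection
        Minimum fraction of a population's cells expressing a gene for the
        gene to count as expressed there (boundary inclusive).  Default 0.10.
    min_path_weight
        Minimum path weight retained when summing w_st (boundary inclusive).
        Default 1.5, which removes down-regulated connections.
    m
        Number of randomized networks for the null.  Default 100,000.
    alpha
        Significance threshold on the BH-adjusted p-value.  Default 0.01.
    include_self_pairs
        Whether autocrine (source == target) pairs are tested.  Default True.
    """

    min_detection: float = 0.10
    min_path_weight: float = 1.5
    m: int = 100_000
    alpha: float = 0.01
    seed: int | None = None
    include_self_pairs: bool = True
    pseudocount: float = 1.0
    log_scale_means: bool = False
    chunk: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_detection <= 1.0:
            raise ValueError("min_detection must be in [0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


def validate_lr_map(lr_map: pd.DataFrame) -> pd.DataFrame:
    """Validate a ligand-receptor map (ligand, receptor, ppi_weight)."""
    required = ("ligand", "receptor", "ppi_weight")
    missing = [c for c in required if c not in lr_map.columns]
    if missing:
        raise ValueError(f"ligand-receptor map missing column(s): {', '.join(missing)}")
    if len(lr_map) == 0:
        raise ValueError("ligand-receptor map is empty")
    if lr_map.duplicated(subset=["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) pairs in map")
    w = lr_map["ppi_weight"].to_numpy(dtype=float)
    if np.any((w < 0) | (w > 1)) or np.any(~np.isfinite(w)):
        raise ValueError("ppi_weight values must lie in [0, 1]")
    return lr_map


def enumerate_candidate_paths(
    profile: PopulationProfile,
    lr_map: pd.DataFrame,
    populations: list | None = None,
    min_detection: float = 0.10,
    include_self_pairs: bool = True,
) -> pd.DataFrame:
    """All candidate source→ligand→receptor→target paths.

    A path is a candidate when the ligand is detected in at least
    ``min_detection`` of the source's cells and the receptor in at least
    ``min_detection`` of the target's cells.  Map pairs whose genes are
    absent from the expression data are skipped with a logged warning.
    """
    validate_lr_map(lr_map)
    if populations is None:
        populations = profile.populations
    genes = set(profile.genes)
    present = lr_map["ligand"].isin(genes) & lr_map["receptor"].isin(genes)
    if (~present).any():
        skipped = lr_map.loc[~present]
        logger.warning(
            "skipping %d ligand-receptor pair(s) with gene(s) absent from the "
            "expression matrix (e.g. %s:%s)",
            len(skipped),
            skipped.iloc[0]["ligand"],
            skipped.iloc[0]["receptor"],
        )
        lr_map = lr_map.loc[present]
    if len(lr_map) == 0:
        raise ValueError("no ligand-receptor pair has both genes in the expression matrix")

    ligands = lr_map["ligand"].to_numpy()
    receptors = lr_map["receptor"].to_numpy()
    ppi = lr_map["ppi_weight"].to_numpy(dtype=float)

    det = profile.detection
    fc = profile.log2fc
    lig_det = det.loc[ligands]  # pairs × populations
    rec_det = det.loc[receptors]
    lig_fc = fc.loc[ligands]
    rec_fc = fc.loc[receptors]

    records = []
    for source in populations:
        lig_ok = lig_det[source].to_numpy() >= min_detection
        for target in populations:
            if source == target and not include_self_pairs:
                continue
            rec_ok = rec_det[target].to_numpy() >= min_detection
            keep = lig_ok & rec_ok
            if not keep.any():
                continue
            w_sl = lig_fc[source].to_numpy()[keep]
            w_rt = rec_fc[target].to_numpy()[keep]
            w_lr = ppi[keep]
            records.append(
                pd.DataFrame(
                    {
                        "source": source,
                        "ligand": ligands[keep],
                        "receptor": receptors[keep],
                        "target": target,
                        "w_source_ligand": w_sl,
                        "w_lr": w_lr,
                        "w_receptor_target": w_rt,
                        "path_weight": w_sl + w_lr + w_rt,
                    }
                )
            )
    if not records:
        return pd.DataFrame(columns=PATH_COLUMNS)
    return pd.concat(records, ignore_index=True)[PATH_COLUMNS]


def filter_paths(paths: pd.DataFrame, min_path_weight: float = 1.5) -> pd.DataFrame:
    """Retain paths with weight ≥ ``min_path_weight`` (boundary inclusive)."""
    if len(paths) == 0:
        return paths.copy()
    return paths.loc[paths["path_weight"] >= min_path_weight].copy()


def summed_weight(paths: pd.DataFrame) -> float:
    """Sum of path weights for one (source, target) pair; 0 for the empty set."""
    if len(paths) == 0:
        return 0.0
    pairs = paths[["source", "target"]].drop_duplicates()
    if len(pairs) > 1:
        raise ValueError("summed_weight expects paths of a single (source, target) pair")
    return float(paths["path_weight"].sum())


def permutation_pvalue(
    w_observed: float,
    ppi_weights: np.ndarray,
    ligand_pool: np.ndarray,
    receptor_pool: np.ndarray,
    m: int,
    min_path_weight: float,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> float:
    """Empirical p-value of an observed w_st against the randomized null.

    Each of the ``m`` randomized networks keeps the pair's T PPI weights,
    pairs them index-wise with T ligand and T receptor fold-changes drawn
    with replacement from the pools, applies the path-weight filter and
    sums.  P_w is the fraction of randomized sums ≥ the observed sum (ties
    count).  T = 0 returns 1.0 by convention: no candidate communication.
    """
    ppi_weights = np.asarray(ppi_weights, dtype=float)
    T = len(ppi_weights)
    if T == 0:
        return 1.0
    ligand_pool = np.asarray(ligand_pool, dtype=float)
    receptor_pool = np.asarray(receptor_pool, dtype=float)
    if len(ligand_pool) == 0 or len(receptor_pool) == 0:
        raise ValueError("fold-change pools must be non-empty")
    hits = 0
    done = 0
    while done < m:
        rows = min(chunk, m - done)
        li = rng.integers(0, len(ligand_pool), size=(rows, T))
        ri = rng.integers(0, len(receptor_pool), size=(rows, T))
        w = ligand_pool[li] + ppi_weights[np.newaxis, :] + receptor_pool[ri]
        w_i = np.where(w >= min_path_weight, w, 0.0).sum(axis=1)
        hits += int((w_i >= w_observed).sum())
        done += rows
    return hits / m


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (values clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fold_change_pools(
    profile: PopulationProfile,
    lr_map: pd.DataFrame,
    min_detection: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Null pools: detected (population, gene) fold-changes, gene restricted
    to the map's ligand side / receptor side, pooled across populations."""
    genes = set(profile.genes)
    lig_genes = sorted(set(lr_map["ligand"]) & genes)
    rec_genes = sorted(set(lr_map["receptor"]) & genes)
    lig_mask = profile.detection.loc[lig_genes] >= min_detection
    rec_mask = profile.detection.loc[rec_genes] >= min_detection
    lig_pool = profile.log2fc.loc[lig_genes].to_numpy()[lig_mask.to_numpy()]
    rec_pool = profile.log2fc.loc[rec_genes].to_numpy()[rec_mask.to_numpy()]
    return lig_pool, rec_pool


def shuffle_fold_changes(
    profile: PopulationProfile, rng: np.random.Generator
) -> PopulationProfile:
    """Globally permute the (gene, population) fold-change values.

    Detection rates are untouched, so the candidate path structure is
    preserved while every source→ligand and receptor→target edge weight is
    drawn from the global fold-change distribution.  Running the test on
    such a profile is the null-calibration experiment: the observed summed
    weights become exchangeable with the randomized-network draws, so
    P_w is approximately uniform.
    """
    fc = profile.log2fc.to_numpy().ravel().copy()
    rng.shuffle(fc)
    shuffled = pd.DataFrame(
        fc.reshape(profile.log2fc.shape),
        index=profile.log2fc.index,
        columns=profile.log2fc.columns,
    )
    return PopulationProfile(detection=profile.detection.copy(), log2fc=shuffled)


def lrnet_test_from_profile(
    profile: PopulationProfile,
    lr_map: pd.DataFrame,
    config: LrnetConfig = LrnetConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Communication-network test from precomputed population profiles.

    Returns ``(results, filtered_paths)``: one row per ordered (source,
    target) pair with T > 0 carrying T, the filtered path count, w_st, the
    permutation P_w, the BH-adjusted p and the significance flag at
    ``config.alpha``; and the filtered four-layer path table behind the
    summed weights.
    """
    populations = profile.populations
    if len(populations) < 2:
        raise ValueError("at least two populations are required")

    candidates = enumerate_candidate_paths(
        profile,
        lr_map,
        populations,
        min_detection=config.min_detection,
        include_self_pairs=config.include_self_pairs,
    )
    filtered = filter_paths(candidates, config.min_path_weight)
    lig_pool, rec_pool = _fold_change_pools(profile, lr_map, config.min_detection)

    grouped = dict(tuple(candidates.groupby(["source", "target"], sort=True)))
    pair_keys = sorted(grouped)
    seeds = np.random.SeedSequence(config.seed).spawn(len(pair_keys))

    rows = []
    for key, seed_seq in zip(pair_keys, seeds):
        paths = grouped[key]
        kept = filter_paths(paths, config.min_path_weight)
        w_st = float(kept["path_weight"].sum())
        p_w = permutation_pvalue(
            w_st,
            paths["w_lr"].to_numpy(),
            lig_pool,
            rec_pool,
            m=config.m,
            min_path_weight=config.min_path_weight,
            rng=np.random.default_rng(seed_seq),
            chunk=config.chunk,
        )
        rows.append(
            {
                "source": key[0],
                "target": key[1],
                "T": len(paths),
                "n_filtered": len(kept),
                "w_st": w_st,
                "p_w": p_w,
            }
        )
    results = pd.DataFrame(rows, columns=EDGE_COLUMNS[:6])
    if len(results):
        results["p_adj"] = bh_adjust(results["p_w"].to_numpy())
        results["significant"] = results["p_adj"] < config.alpha
    else:
        results["p_adj"] = []
        results["significant"] = []
    return results, filtered.reset_index(drop=True)


def lrnet_test(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    lr_map: pd.DataFrame,
    config: LrnetConfig = LrnetConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full communication-network test from raw counts and annotations.

    Normalizes (if needed), computes per-population detection and
    fold-change profiles on the aggregate cohort (all conditions pooled),
    and delegates to :func:`lrnet_test_from_profile`.
    """
    if not matrix.normalized:
        matrix = normalize_cptt_log(matrix)
    profile = population_profiles(
        matrix,
        annotations,
        pseudocount=config.pseudocount,
        log_scale_means=config.log_scale_means,
    )
    return lrnet_test_from_profile(profile, lr_map, config)


def export_network(
    results: pd.DataFrame,
    paths: pd.DataFrame,
    out_prefix: str,
    significant_only: bool = False,
) -> tuple[str, str]:
    """Write the source→target edge list and the four-layer path table.

    Produces ``<prefix>.edges.tsv`` and ``<prefix>.paths.tsv``, plain TSVs
    importable by generic graph tools (e.g. Cytoscape), with floats at full
    round-trip precision.  With ``significant_only`` both files are
    restricted to significant source→target pairs.
    """
    edges = results
    out_paths = paths
    if significant_only:
        edges = results.loc[results["significant"]]
        keep = set(map(tuple, edges[["source", "target"]].to_numpy()))
        if len(out_paths):
            mask = [
                (s, t) in keep
                for s, t in zip(out_paths["source"], out_paths["target"])
            ]
            out_paths = out_paths.loc[mask]
        else:
            out_paths = out_paths.copy()
    edges_file = f"{out_prefix}.edges.tsv"
    paths_file = f"{out_prefix}.paths.tsv"
    with atomic_write(edges_file) as handle:
        edges.to_csv(handle, sep="\t", index=False, float_format="%.17g")
    with atomic_write(paths_file) as handle:
        out_paths.to_csv(handle, sep="\t", index=False, float_format="%.17g")
    return edges_file, paths_file
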