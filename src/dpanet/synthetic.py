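"""Synthetic scRNA-seq cohorts with known compositional and communication truth.

The generator emulates the statistical structure the two tests assume:
multinomially sampled cluster memberships per condition (with optional
deliberate proportion changes in the second condition) and overdispersed
per-gene UMI counts (negative binomial, per-gene baseline means, per-cell
library-size factors) with planted population-specific ligand/receptor
up-regulation.

Planted communication channels are *marker-style*: a planted ligand gene is
nearly silent everywhere (baseline mean ``marker_baseline``, detection well
below the 10% filter) and expressed in its source population at a mean
sized so that the realized log2 fold-change versus the remaining cells
equals the requested effect; receptors likewise in the target.  Channels
are therefore population-exclusive, which is what makes "exactly this
(source, target) pair communicates" a well-defined ground truth.  Decoy
ligand-receptor pairs use genes expressed everywhere at baseline, so the
detection filter keeps them in the candidate set while their fold-changes
hover around zero.

What this generator does *not* emulate: doublets, ambient RNA, batch
effects, dropout beyond NB zeros, or upstream QC.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .expression import CPTT_SCALE, ExpressionMatrix

__all__ = ["PlantedChannel", "SyntheticDesign", "generate_dataset"]


@dataclass(frozen=True)
class PlantedChannel:
    """One planted source→target communication channel."""

    source: str = "P00"
    target: str = "P01"
    n_lr_pairs: int = 10
    ligand_effect: float = 2.0  # target log2 fold-change of ligands in source
    receptor_effect: float = 2.0
    ppi_weight: float = 0.9

    def __post_init__(self) -> None:
        if self.n_lr_pairs < 1:
            raise ValueError("a planted channel needs n_lr_pairs >= 1")
        if not np.isfinite([self.ligand_effect, self.receptor_effect]).all():
            raise ValueError("planted effects must be finite")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full design of a synthetic cohort.

    Defaults: 12 populations × 2 conditions × 1800 cells (uniform base
    proportions → ~300 cells per population overall), 300 genes, one planted
    channel of 10 ligand-receptor pairs at log2 effect 2.0 plus 50 decoy
    pairs, negative-binomial counts with dispersion 0.5.
    """

    n_populations: int = 12
    cells_per_condition: tuple[int, int] = (1800, 1800)
    base_proportions: tuple | None = None  # None → uniform
    changed_indices: tuple = ()
    change_factors: tuple = ()
    n_genes: int = 300
    nb_dispersion: float = 0.5
    gene_mean_log_sd: float = 0.5  # lognormal sd of baseline gene means (median 1)
    cell_size_log_sd: float = 0.3  # lognormal sd of per-cell library factors
    marker_baseline: float = 0.03  # near-silent baseline of planted genes
    channels: tuple[PlantedChannel, ...] = (PlantedChannel(),)
    n_decoy_pairs: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_genes < 1:
            raise ValueError("degenerate design: need >= 1 population and >= 1 gene")
        if min(self.cells_per_condition) < 1:
            raise ValueError("degenerate design: each condition needs >= 1 cell")
        if len(self.changed_indices) != len(self.change_factors):
            raise ValueError("changed_indices and change_factors must align")
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, float)
            if len(p) != self.n_populations or not np.isclose(p.sum(), 1.0):
                raise ValueError("base_proportions must cover all populations and sum to 1")

    @property
    def populations(self) -> list[str]:
        return [f"P{j:02d}" for j in range(self.n_populations)]

    def proportions(self) -> np.ndarray:
        if self.base_proportions is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        return np.asarray(self.base_proportions, dtype=float)

    def n_planted_genes(self) -> int:
        return sum(ch.n_lr_pairs for ch in self.channels) * 2


def _annotations(design: SyntheticDesign, rng: np.random.Generator) -> pd.DataFrame:
    pops = np.array(design.populations)
    base = design.proportions()
    cond = base.copy()
    for i, f in zip(design.changed_indices, design.change_factors):
        cond[i] *= f
    cond = cond / cond.sum()

    rows = []
    for name, n_cells, props in (
        ("ctrl", design.cells_per_condition[0], base),
        ("case", design.cells_per_condition[1], cond),
    ):
        counts = rng.multinomial(n_cells, props)
        rows.append(
            pd.DataFrame(
                {"condition": name, "cluster": np.repeat(pops, counts)}
            )
        )
    ann = pd.concat(rows, ignore_index=True)
    ann.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(ann))])
    return ann


def _gene_table(design: SyntheticDesign, rng: np.random.Generator):
    """Gene ids, baseline means, planted roles, and the LR map."""
    gene_ids: list[str] = []
    planted_rows = []
    for ci, ch in enumerate(design.channels):
        for k in range(ch.n_lr_pairs):
            lig = f"LG{ci}_{k:03d}"
            rec = f"RC{ci}_{k:03d}"
            gene_ids += [lig, rec]
            planted_rows.append((lig, rec, ch))
    decoy_pairs = []
    for k in range(design.n_decoy_pairs):
        lig = f"DL{k:03d}"
        rec = f"DR{k:03d}"
        gene_ids += [lig, rec]
        decoy_pairs.append((lig, rec))
    n_named = len(gene_ids)
    if n_named > design.n_genes:
        raise ValueError(
            f"design needs at least {n_named} genes for planted + decoy pairs, "
            f"got n_genes={design.n_genes}"
        )
    gene_ids += [f"BG{k:04d}" for k in range(design.n_genes - n_named)]

    means = rng.lognormal(mean=0.0, sigma=design.gene_mean_log_sd, size=design.n_genes)
    # planted genes: near-silent baseline everywhere
    n_planted = design.n_planted_genes()
    means[:n_planted] = design.marker_baseline

    lr_rows = [
        {"ligand": lig, "receptor": rec, "ppi_weight": ch.ppi_weight}
        for lig, rec, ch in planted_rows
    ]
    lr_rows += [
        {"ligand": lig, "receptor": rec, "ppi_weight": round(float(w), 3)}
        for (lig, rec), w in zip(
            decoy_pairs, rng.uniform(0.5, 0.95, size=len(decoy_pairs))
        )
    ]
    return np.array(gene_ids, dtype=object), means, planted_rows, pd.DataFrame(lr_rows)


def _elevated_mean(effect: float, baseline: float, cptt_per_count: float) -> float:
    """Mean count giving a realized log2 FC ≈ ``effect`` on the CPTT+1 scale."""
    target = (cptt_per_count * baseline + 1.0) * 2.0**effect - 1.0
    return max(target, 0.0) / cptt_per_count


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (raw counts, annotations, ligand-receptor map, truth record).

    Deterministic for a fixed ``design.seed``.  The truth record lists the
    planted channels, the deliberately changed populations and the planted
    gene identifiers.
    """
    rng = np.random.default_rng(design.seed)
    ann = _annotations(design, rng)
    gene_ids, base_means, planted_rows, lr_map = _gene_table(design, rng)

    pops = design.populations
    pop_index = {p: i for i, p in enumerate(pops)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # genes × populations mean matrix
    M = np.tile(base_means[:, np.newaxis], (1, len(pops)))
    expected_total = float(base_means.sum())
    cptt_per_count = CPTT_SCALE / expected_total
    for lig, rec, ch in planted_rows:
        M[gene_index[lig], pop_index[ch.source]] = _elevated_mean(
            ch.ligand_effect, design.marker_baseline, cptt_per_count
        )
        M[gene_index[rec], pop_index[ch.target]] = _elevated_mean(
            ch.receptor_effect, design.marker_baseline, cptt_per_count
        )

    r = 1.0 / design.nb_dispersion  # NB size parameter: var = mu + dispersion*mu^2
    n_cells = len(ann)
    counts = np.empty((design.n_genes, n_cells), dtype=np.int64)
    size_factors = rng.lognormal(mean=0.0, sigma=design.cell_size_log_sd, size=n_cells)
    pop_codes = ann["cluster"].map(pop_index).to_numpy()
    for p, pi in pop_index.items():
        cols = np.flatnonzero(pop_codes == pi)
        if len(cols) == 0:
            continue
        mu = M[:, [pi]] * size_factors[np.newaxis, cols]
        counts[:, cols] = rng.negative_binomial(r, r / (r + mu))

    matrix = ExpressionMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        normalized=False,
    )
    truth = {
        "channels": [asdict(ch) for ch in design.channels],
        "changed_populations": {
            pops[i]: f for i, f in zip(design.changed_indices, design.change_factors)
        },
        "planted_ligands": [lig for lig, _, _ in planted_rows],
        "planted_receptors": [rec for _, rec, _ in planted_rows],
        "n_decoy_pairs": design.n_decoy_pairs,
        "seed": design.seed,
    }
    return matrix, ann, lr_map, truth
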