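"""Expression-matrix conventions used by the communication network.

Three primitives: counts-per-ten-thousand log normalization, per-population
detection rate, and log2 fold-change of a gene in one population versus all
remaining cells.  Fold-changes follow the convention of classic single-cell
toolkits: means are taken on the linear (de-logged, i.e. CPTT) scale with a
pseudo-count of 1 on both sides,

    log2fc = log2((mean_in + 1) / (mean_rest + 1)),

so that weakly expressed genes shrink toward 0.  A switch to means over the
log-transformed values is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "normalize_cptt_log",
    "detection_rate",
    "log2fc_vs_rest",
    "PopulationProfile",
    "population_profiles",
]

CPTT_SCALE = 10_000.0


@dataclass
class ExpressionMatrix:
    """A genes × cells expression matrix with aligned identifier lists.

    ``values`` may be a dense :class:`numpy.ndarray` or a scipy sparse
    matrix.  ``normalized`` records whether values are log1p-CPTT
    (True) or raw counts (False).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            raise KeyError(f"gene not in matrix: {gene!r}")
        return int(hits[0])

    def cell_totals(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)


def normalize_cptt_log(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-ten-thousand, log-transformed: v ↦ ln(1 + 10000·v/s).

    ``s`` is the cell's total count.  Cells with zero total counts are an
    error (they cannot be normalized) and are reported by identifier.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    totals = matrix.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        names = ", ".join(map(str, matrix.cell_ids[zero[:5]]))
        raise ValueError(f"cell(s) with zero total counts cannot be normalized: {names}")
    scale = CPTT_SCALE / totals
    if sp.issparse(matrix.values):
        vals = matrix.values.tocsc(copy=True).astype(np.float64)
        vals = vals @ sp.diags(scale)
        vals.data = np.log1p(vals.data)
        vals = vals.tocsr()
    else:
        vals = np.log1p(matrix.values * scale[np.newaxis, :])
    return replace(matrix, values=vals, normalized=True)


def detection_rate(
    matrix: ExpressionMatrix, cell_mask: np.ndarray, gene: str
) -> float:
    """Fraction of the masked cells with nonzero expression of ``gene``.

    Invariant under any monotone positive transform of the values, so it can
    be computed on raw or normalized matrices interchangeably.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty population: no cells selected")
    g = matrix.gene_index(gene)
    row = matrix.values[g]
    if sp.issparse(matrix.values):
        row = np.asarray(row.todense()).ravel()
    return float((row[cell_mask] > 0).mean())


def log2fc_vs_rest(
    matrix: ExpressionMatrix,
    cell_mask: np.ndarray,
    gene: str,
    pseudocount: float = 1.0,
    log_scale_means: bool = False,
) -> float:
    """log2 fold-change of ``gene`` in the masked population versus the rest.

    The matrix must be normalized.  By default means are taken on the linear
    CPTT scale (``expm1`` of the stored log values); ``log_scale_means=True``
    averages the log values directly instead.
    """
    if not matrix.normalized:
        raise ValueError("log2fc_vs_rest requires a normalized matrix")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty population: no cells selected")
    if cell_mask.all():
        raise ValueError("population equals the entire cohort: empty complement")
    g = matrix.gene_index(gene)
    row = matrix.values[g]
    if sp.issparse(matrix.values):
        row = np.asarray(row.todense()).ravel()
    vals = row if log_scale_means else np.expm1(row)
    mean_in = float(vals[cell_mask].mean())
    mean_rest = float(vals[~cell_mask].mean())
    return float(np.log2((mean_in + pseudocount) / (mean_rest + pseudocount)))


@dataclass
class PopulationProfile:
    """Per-(gene, population) detection rates and log2 fold-changes.

    Both frames are genes × populations, sharing index and columns.
    """

    detection: pd.DataFrame
    log2fc: pd.DataFrame

    @property
    def populations(self) -> list:
        return list(self.detection.columns)

    @property
    def genes(self) -> pd.Index:
        return self.detection.index


def population_profiles(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    pseudocount: float = 1.0,
    log_scale_means: bool = False,
) -> PopulationProfile:
    """Detection rate and log2fc-vs-rest for every gene in every population.

    Populations are the cluster labels of ``annotations`` pooled over all
    conditions (the network is built on the aggregate cohort).  The
    annotation's ``cell_id`` order must match the matrix columns.
    """
    if not matrix.normalized:
        raise ValueError("population_profiles requires a normalized matrix")
    ann = annotations.set_index("cell_id").loc[list(matrix.cell_ids)]
    clusters = sorted(ann["cluster"].unique())
    X = matrix.dense()
    linear = X if log_scale_means else np.expm1(X)
    nonzero = X > 0

    det = {}
    fc = {}
    total_sum = linear.sum(axis=1)
    n_total = matrix.n_cells
    for pop in clusters:
        mask = (ann["cluster"] == pop).to_numpy()
        n_in = int(mask.sum())
        n_rest = n_total - n_in
        if n_rest == 0:
            raise ValueError("a single population covers the entire cohort")
        det[pop] = nonzero[:, mask].mean(axis=1)
        sum_in = linear[:, mask].sum(axis=1)
        mean_in = sum_in / n_in
        mean_rest = (total_sum - sum_in) / n_rest
        fc[pop] = np.log2((mean_in + pseudocount) / (mean_rest + pseudocount))

    index = pd.Index(matrix.gene_ids, name="gene")
    return PopulationProfile(
        detection=pd.DataFrame(det, index=index),
        log2fc=pd.DataFrame(fc, index=index),
    )
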