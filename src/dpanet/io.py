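"""Readers and writers for the interchange formats.

Formats:

* annotations — TSV with header ``cell_id<TAB>condition<TAB>cluster``;
* expression — a Matrix Market triplet directory (``matrix.mtx`` or
  ``matrix.mtx.gz`` plus ``genes.tsv``/``features.tsv`` and
  ``barcodes.tsv``), or a dense delimited file (genes as rows, first
  column gene ids, header row of cell ids);
* ligand-receptor map — TSV with header ``ligand<TAB>receptor<TAB>ppi_weight``.

All writers go through :func:`atomic_write`: output lands under its final
name only when fully written (temp file + rename), so a failed run leaves
no partial files behind.
"""

from __future__ import annotations

import contextlib
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .annotations import validate_annotations
from .expression import ExpressionMatrix

__all__ = [
    "atomic_write",
    "read_annotations",
    "write_annotations",
    "read_matrix",
    "write_matrix_market",
    "write_dense_csv",
    "read_lr_map",
    "write_lr_map",
]


@contextlib.contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell annotation TSV."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"annotation file is empty: {path}") from None
    return validate_annotations(frame)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        annotations.to_csv(handle, sep="\t", index=False)


def _read_sidecar_ids(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].to_numpy(dtype=object)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix (Matrix Market directory or dense CSV/TSV).

    Integer counts are preserved exactly.  Dimension disagreement between
    the matrix and its sidecar identifier files is an error.
    """
    path = Path(path)
    if path.is_dir():
        mtx = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / name).exists():
                mtx = path / name
                break
        if mtx is None:
            raise ValueError(f"no matrix.mtx(.gz) found in directory: {path}")
        genes_file = None
        for name in ("genes.tsv", "features.tsv"):
            if (path / name).exists():
                genes_file = path / name
                break
        if genes_file is None:
            raise ValueError(f"no genes.tsv/features.tsv found in directory: {path}")
        barcodes_file = path / "barcodes.tsv"
        if not barcodes_file.exists():
            raise ValueError(f"no barcodes.tsv found in directory: {path}")
        values = scipy.io.mmread(mtx).tocsr()
        gene_ids = _read_sidecar_ids(genes_file)
        cell_ids = _read_sidecar_ids(barcodes_file)
        if values.shape[0] != len(gene_ids):
            raise ValueError(
                f"matrix has {values.shape[0]} rows but {genes_file.name} lists "
                f"{len(gene_ids)} genes"
            )
        if values.shape[1] != len(cell_ids):
            raise ValueError(
                f"matrix has {values.shape[1]} columns but barcodes.tsv lists "
                f"{len(cell_ids)} cells"
            )
        return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)
    # dense: first column gene ids, header row cell ids
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    values = frame.to_numpy()
    if np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    return ExpressionMatrix(
        values=values,
        gene_ids=frame.index.to_numpy(dtype=object),
        cell_ids=frame.columns.to_numpy(dtype=object),
    )


def write_matrix_market(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write a Matrix Market triplet directory (matrix.mtx, genes.tsv, barcodes.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values = matrix.values
    if not sp.issparse(values):
        values = sp.coo_matrix(values)
    tmp = out_dir / ".tmp.matrix.mtx"
    scipy.io.mmwrite(str(tmp), values)
    os.replace(tmp, out_dir / "matrix.mtx")
    with atomic_write(out_dir / "genes.tsv") as handle:
        for g in matrix.gene_ids:
            handle.write(f"{g}\n")
    with atomic_write(out_dir / "barcodes.tsv") as handle:
        for c in matrix.cell_ids:
            handle.write(f"{c}\n")


def write_dense_csv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids
    )
    frame.index.name = "gene"
    with atomic_write(path) as handle:
        frame.to_csv(handle, float_format="%.17g")


def read_lr_map(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor map TSV (ligand, receptor, ppi_weight)."""
    from .lrnet import validate_lr_map  # local import to avoid a cycle

    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"ligand-receptor map file is empty: {path}") from None
    return validate_lr_map(frame)


def write_lr_map(lr_map: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        lr_map.to_csv(handle, sep="\t", index=False, float_format="%.17g")
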