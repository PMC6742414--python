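"""Reading and writing expression matrices and clustering results.

All downstream modules consume only the in-memory :class:`ExpressionMatrix`;
this module is the single place where on-disk formats are interpreted.
Supported inputs are dense CSV/TSV tables (cells in the header row, genes in
the first column, with a ``genes_as`` flag for transposed files) and Matrix
Market triplets with ``genes.tsv`` / ``barcodes.tsv`` side files in the 10x
CellRanger v1/v2 layout. Values are kept exactly as supplied; normalization
policy lives elsewhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import mmread

from .exceptions import MatrixFormatError, MatrixValidationError
from .partition import Partition

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "write_partition",
    "read_partition",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells table of nonnegative expression values.

    Invariants (checked at construction): shape matches the id lists, all
    values are finite and >= 0, and neither id list contains duplicates.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D genes x cells array")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids):
            raise MatrixValidationError(
                f"{n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise MatrixValidationError(
                f"{n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("non-finite expression values")
        if np.any(self.values < 0):
            raise MatrixValidationError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.cell_ids)
        )

    def subset_cells(self, indices) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx]
        )


def _read_dense(path: str, sep: str, genes_as: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
    except (pd.errors.ParserError, ValueError) as exc:
        raise MatrixFormatError(f"could not parse {path}: {exc}") from exc
    if genes_as == "columns":
        df = df.T
        values = values.T
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def _read_mtx10x(path: str) -> ExpressionMatrix:
    # `path` is either the .mtx file or the directory holding the triplet.
    if os.path.isdir(path):
        mtx_path = os.path.join(path, "matrix.mtx")
        folder = path
    else:
        mtx_path = path
        folder = os.path.dirname(path) or "."
    genes_path = os.path.join(folder, "genes.tsv")
    barcodes_path = os.path.join(folder, "barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not os.path.exists(p):
            raise MatrixFormatError(f"missing file for mtx10x input: {p}")
    try:
        mat = mmread(mtx_path)
    except ValueError as exc:
        raise MatrixFormatError(f"could not parse {mtx_path}: {exc}") from exc
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    gene_ids = [str(g) for g in genes.iloc[:, 0]]
    cell_ids = [str(b) for b in barcodes.iloc[:, 0]]
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise MatrixFormatError(
            f"matrix shape {values.shape} does not match "
            f"{len(gene_ids)} genes x {len(cell_ids)} barcodes"
        )
    return ExpressionMatrix(values, gene_ids, cell_ids)


def read_expression(
    path: str, format: str = "csv", genes_as: str = "rows"
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        File to read (for ``mtx10x``: the ``.mtx`` file or its directory,
        with ``genes.tsv`` and ``barcodes.tsv`` co-located).
    format
        One of ``csv``, ``tsv``, ``mtx10x``.
    genes_as
        Whether on-disk rows are genes (``rows``, default) or cells
        (``columns``). Ignored for ``mtx10x``, which is genes x cells by
        convention.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if genes_as not in ("rows", "columns"):
        raise ValueError(f"genes_as must be 'rows' or 'columns', got {genes_as!r}")
    if format == "csv":
        return _read_dense(path, ",", genes_as)
    if format == "tsv":
        return _read_dense(path, "\t", genes_as)
    if format == "mtx10x":
        return _read_mtx10x(path)
    raise ValueError(f"unknown format {format!r}")


def write_expression(
    E: ExpressionMatrix, path: str, format: str = "csv", genes_as: str = "rows"
) -> None:
    """Write a dense CSV/TSV matrix readable by :func:`read_expression`."""
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    df = pd.DataFrame(E.values, index=E.gene_ids, columns=E.cell_ids)
    if genes_as == "columns":
        df = df.T
    df.to_csv(path, sep=sep)


def write_partition(partition: Partition, path: str) -> None:
    """Write a partition as a TSV with cell_id, cluster_label, iteration_found."""
    if partition.n_cells == 0:
        raise ValueError("cannot write an empty partition")
    rows = [
        (cell, label, partition.iteration_found.get(label, 1))
        for cell, label in partition.labels.items()
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "cluster_label", "iteration_found"])
    df.to_csv(path, sep="\t", index=False)


def read_partition(path: str) -> Partition:
    """Re-read a partition written by :func:`write_partition`."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    labels = dict(zip(df["cell_id"], df["cluster_label"].astype(int)))
    iteration = {
        int(l): int(i)
        for l, i in zip(df["cluster_label"], df["iteration_found"])
    }
    return Partition(labels=labels, iteration_found=iteration)
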