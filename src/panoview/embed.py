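"""The 3-D PCA embedding consumed by OLMC in every iteration.

Cells are projected onto the first three principal components of the
cells x variable-genes submatrix. Genes are centered but not scaled by
default (distances in PC space drive the clustering, so this is a recorded
convention, switchable via ``scale_genes``). The exact SVD solver is used so
coordinates are reproducible bit-for-bit at these problem sizes; the result
is deterministic up to per-component sign, and all downstream steps use
Euclidean distances only, hence are sign-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DegenerateInputError
from .matrix_io import ExpressionMatrix

__all__ = ["PointCloud3", "pca3"]


@dataclass
class PointCloud3:
    """N x d coordinates (d = 3 for PCA output) with their cell ids."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords rows must match cell_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


def pca3(
    E: ExpressionMatrix, variable_genes, *, scale_genes: str = "none"
) -> PointCloud3:
    """Project cells onto the top three principal components.

    Parameters
    ----------
    E
        Expression matrix (genes x cells).
    variable_genes
        Indices of the genes spanning the space to embed.
    scale_genes
        ``"none"`` (default, centering only) or ``"unit"`` (divide each
        gene by its standard deviation before the SVD).
    """
    vg = np.asarray(variable_genes, dtype=int)
    if E.n_cells < 4:
        raise DegenerateInputError("pca3 needs at least 4 cells")
    if vg.size < 3:
        raise DegenerateInputError("pca3 needs at least 3 variable genes")
    X = E.values[vg].T  # cells x genes
    if scale_genes == "unit":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    elif scale_genes != "none":
        raise ValueError(f"scale_genes must be 'none' or 'unit', got {scale_genes!r}")
    pca = PCA(n_components=3, svd_solver="full")
    coords = pca.fit_transform(X)
    return PointCloud3(coords, list(E.cell_ids))
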