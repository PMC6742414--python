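"""Synthetic expression datasets: isotropic Gaussian blobs in gene space.

The generator draws 500 cells in a 20,000-dimensional gene space, split as
evenly as possible across ``n_centers`` isotropic Gaussian clusters whose
centers are uniform in ``(-10, 10)`` per gene, then rescales all values by
one global min-max affine map onto [0, 10000] so the matrix is a
nonnegative expression table. The rare-cell variant removes 90% (rounded
down) of one randomly chosen cluster, leaving a rare subpopulation of about
0.6%-3% of the cells.

Two sweep iterators reproduce the benchmark families: the main sweep of
1,200 datasets (n_centers 3-22 x SD {0.5, 1, 2} x 20 replicates) and the
rare sweep of 260 datasets (n_centers 3-15, SD 1, 20 replicates). Every
config carries an explicit seed, distinct across a sweep, so both families
replay exactly.

These blobs are deliberately idealized: they carry no dropout, library-size
variation or count noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.datasets import make_blobs

from .matrix_io import ExpressionMatrix

__all__ = [
    "BlobConfig",
    "RareConfig",
    "raw_blob_coords",
    "generate_blobs",
    "generate_rare",
    "sweep_main",
    "sweep_rare",
]

_RARE_CHOICE_OFFSET = 500_000  # decouples cluster choice from blob layout


@dataclass(frozen=True)
class BlobConfig:
    n_centers: int
    cluster_sd: float
    seed: int
    n_cells: int = 500
    n_genes: int = 20_000
    center_box: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_centers < 2:
            raise ValueError("n_centers must be >= 2")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")


@dataclass(frozen=True)
class RareConfig:
    base: BlobConfig
    rare_keep_fraction: float = 0.10
    rare_cluster_choice_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.rare_keep_fraction < 1:
            raise ValueError("rare_keep_fraction must be in (0, 1)")
        if not 3 <= self.base.n_centers <= 15:
            raise ValueError("rare datasets use n_centers in [3, 15]")

    @property
    def choice_seed(self) -> int:
        if self.rare_cluster_choice_seed is not None:
            return self.rare_cluster_choice_seed
        return self.base.seed + _RARE_CHOICE_OFFSET


def _cell_ids(n: int) -> list[str]:
    return [f"cell{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def raw_blob_coords(cfg: BlobConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unrescaled cells x genes blob coordinates and their labels.

    Raw coordinates can be negative; this is the debugging view behind
    :func:`generate_blobs`, which applies the global [0, 10000] rescale.
    """
    X, labels = make_blobs(
        n_samples=cfg.n_cells,
        n_features=cfg.n_genes,
        centers=cfg.n_centers,
        cluster_std=cfg.cluster_sd,
        center_box=cfg.center_box,
        shuffle=True,
        random_state=cfg.seed,
    )
    return X, np.asarray(labels, dtype=int)


def generate_blobs(cfg: BlobConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate one blob dataset; returns the matrix and truth labels."""
    X, labels = raw_blob_coords(cfg)
    lo, hi = X.min(), X.max()
    X = (X - lo) / (hi - lo) * 10_000.0
    E = ExpressionMatrix(
        X.T, gene_ids=_gene_ids(cfg.n_genes), cell_ids=_cell_ids(cfg.n_cells)
    )
    return E, labels


def generate_rare(cfg: RareConfig) -> tuple[ExpressionMatrix, np.ndarray, int]:
    """Generate a rare-cell dataset.

    Returns the down-sampled matrix, the truth labels of the surviving
    cells, and the label of the rare cluster. floor(0.9 * size) cells of
    the randomly chosen cluster are removed, so e.g. a 50-cell cluster
    keeps 5 cells.
    """
    E, labels = generate_blobs(cfg.base)
    rng = np.random.default_rng(cfg.choice_seed)
    rare_label = int(rng.integers(cfg.base.n_centers))
    members = np.flatnonzero(labels == rare_label)
    remove_frac = 1.0 - cfg.rare_keep_fraction
    n_remove = int(np.floor(remove_frac * members.size))
    if n_remove >= members.size:
        raise ValueError("rare cluster would be empty after down-sampling")
    removed = rng.choice(members, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(cfg.base.n_cells), removed)
    return E.subset_cells(keep), labels[keep], rare_label


def sweep_main(n_replicates: int = 20, base_seed: int = 0) -> Iterator[BlobConfig]:
    """The main benchmark family: n_centers 3-22 x SD {0.5, 1, 2}.

    Defaults yield the full 1,200-dataset sweep with distinct seeds
    ``base_seed .. base_seed + 1199``.
    """
    counter = 0
    for n_centers in range(3, 23):
        for sd in (0.5, 1.0, 2.0):
            for _ in range(n_replicates):
                yield BlobConfig(
                    n_centers=n_centers, cluster_sd=sd, seed=base_seed + counter
                )
                counter += 1


def sweep_rare(n_replicates: int = 20, base_seed: int = 0) -> Iterator[RareConfig]:
    """The rare-cell family: n_centers 3-15, SD 1; defaults yield 260 configs."""
    counter = 0
    for n_centers in range(3, 16):
        for _ in range(n_replicates):
            yield RareConfig(
                base=BlobConfig(
                    n_centers=n_centers, cluster_sd=1.0, seed=base_seed + counter
                )
            )
            counter += 1
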