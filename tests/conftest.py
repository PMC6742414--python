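"""Shared fixtures: small matrices and seeded point clouds."""

import numpy as np
import pytest

from panoview import ExpressionMatrix
from panoview.embed import PointCloud3


def make_matrix(values, prefix=("g", "c")) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        gene_ids=[f"{prefix[0]}{i}" for i in range(values.shape[0])],
        cell_ids=[f"{prefix[1]}{j}" for j in range(values.shape[1])],
    )


def make_cloud(coords) -> PointCloud3:
    coords = np.asarray(coords, dtype=float)
    return PointCloud3(coords, [f"p{i}" for i in range(coords.shape[0])])


def gaussian_modes(centers, n_per_mode, sd, seed) -> tuple[PointCloud3, np.ndarray]:
    """Seeded isotropic Gaussian modes in 2-D or 3-D with truth labels."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    pts, labels = [], []
    for k, c in enumerate(centers):
        pts.append(c + sd * rng.standard_normal((n_per_mode, centers.shape[1])))
        labels.extend([k] * n_per_mode)
    coords = np.vstack(pts)
    return make_cloud(coords), np.array(labels)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return make_matrix(rng.uniform(0, 10, size=(30, 12)))
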