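"""Ordering Local Maximum by Convex hull (OLMC): density clustering.

OLMC clusters a low-dimensional point cloud (here: cells in 3-D PCA space)
in four stages:

1. *Radius estimation.* Pairwise Euclidean distances are histogrammed into
   ``bc`` equal-width bins; the bin interval ``R_c = (d_max - d_min) / bc``
   becomes the neighborhood radius.
2. *Density ranking.* Each cell's local density is its number of neighbors
   within ``R_c`` (closed ball, self excluded); cells are ranked by
   decreasing count, ``P_1`` being the global density maximum.
3. *Local-maximum discovery.* The first group is seeded from the cells in
   the first of ``bg`` equal-width bins of the distance-to-``P_1``
   histogram (the histogram range spans the whole cloud, so the bin width
   is a property of the data, not of the scan state), and its convex hull
   is built. Walking down the density ranking, the next unassigned cell
   ``P_m`` is compared against every live group: with ``R_Pm^H`` the
   distance to the group's nearest hull vertex and ``Rbar_H`` the mean
   pairwise distance among that hull's vertices, ``P_m`` joins the group
   minimizing ``R_Pm^H`` among those with ``R_Pm^H < Rbar_H`` (expanding
   its hull); otherwise ``P_m`` is a new local maximum and seeds its own
   group from its first distance bin. The search ends when a hull can no
   longer be constructed — fewer than dim + 1 cells unassigned, or fewer
   than dim + 1 in the candidate's seed bin. This ending rule is what
   saturates the maxima count as ``bg`` grows: past a data-dependent bin
   size, seeds become too sparse to found further groups. Rank-deficient
   seeds of sufficient size fall back to the affine-subspace hull (a 2-D
   hull or segment endpoints).
4. *Assignment.* Cells absorbed by a group keep its label; every remaining
   cell is assigned to the nearest local-maximum peak.

The number of histogram bins ``bg`` controls how many local maxima can be
resolved. When the cloud is small enough (< ``cell_number`` points), ``bg``
is chosen by a saturation scan: increase the bin count in steps of 5 until
the number of discovered maxima stops growing, capped at 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from .embed import PointCloud3
from .exceptions import DegenerateInputError
from .partition import Partition

__all__ = [
    "OlmcParams",
    "DensityField",
    "MaximaGroup",
    "OlmcDetails",
    "neighbor_radius",
    "density_ranking",
    "find_local_maxima",
    "optimize_bin_size",
    "assign_to_maxima",
    "olmc_cluster",
]

logger = logging.getLogger("panoview")


@dataclass(frozen=True)
class OlmcParams:
    """OLMC knobs with their defaults.

    bc
        Bins of the pairwise-distance histogram defining the neighborhood
        radius ``R_c`` (default 20).
    bg
        Bins of the distance-to-peak histograms seeding convex hulls
        (default 20; used directly when the saturation scan is skipped).
    bg_step, maxbb
        The saturation scan tries ``bg = bg_step, 2*bg_step, ...,
        bg_step * maxbb`` (defaults 5 and 20, i.e. a ceiling of 100).
    cell_number
        The scan runs only below this point count (default 1000); larger
        clouds use the default ``bg``.
    radius_convention
        ``"range"`` (default): ``R_c = (d_max - d_min)/bc``, the observed-
        range histogram interval. ``"max"``: ``d_max/bc`` dialect.
    """

    bc: int = 20
    bg: int = 20
    bg_step: int = 5
    maxbb: int = 20
    cell_number: int = 1000
    radius_convention: str = "range"

    def __post_init__(self) -> None:
        for name in ("bc", "bg", "bg_step", "maxbb", "cell_number"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.radius_convention not in ("range", "max"):
            raise ValueError("radius_convention must be 'range' or 'max'")


@dataclass
class DensityField:
    """Per-cell neighbor counts within ``R_c`` and the density ranking."""

    radius_rc: float
    neighbor_counts: np.ndarray
    ranking: np.ndarray  # permutation of 0..N-1, decreasing count

    def __post_init__(self) -> None:
        self.neighbor_counts = np.asarray(self.neighbor_counts, dtype=int)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if self.radius_rc <= 0:
            raise ValueError("radius_rc must be positive")
        n = self.neighbor_counts.size
        if sorted(self.ranking) != list(range(n)):
            raise ValueError("ranking must be a permutation of 0..N-1")
        ranked = self.neighbor_counts[self.ranking]
        if np.any(np.diff(ranked) > 0):
            raise ValueError("ranking must order counts non-increasingly")


@dataclass
class MaximaGroup:
    """One local density maximum with its members and current hull."""

    peak_index: int
    member_indices: np.ndarray
    hull_vertices: np.ndarray  # coordinates of the hull's vertex points

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        if self.peak_index not in self.member_indices:
            raise ValueError("peak must be a member of its group")


@dataclass(frozen=True)
class OlmcDetails:
    """Diagnostics of one OLMC run (for the engine's iteration log)."""

    radius_rc: float
    bg_used: int
    n_maxima: int


def neighbor_radius(points: PointCloud3, bc: int = 20, *, convention: str = "range") -> float:
    """Estimate the neighborhood radius ``R_c`` from the distance histogram.

    ``R_c`` is the bin interval of a ``bc``-bin equal-width histogram of all
    pairwise Euclidean distances: ``(d_max - d_min) / bc`` under the default
    observed-range convention, ``d_max / bc`` under the ``"max"`` dialect.
    """
    if points.n_points < 2:
        raise DegenerateInputError("need at least 2 points")
    d = pdist(points.coords)
    d_max = float(d.max())
    d_min = float(d.min())
    if convention == "max":
        if d_max == 0:
            raise DegenerateInputError("all points coincident")
        return d_max / bc
    if d_max == d_min:
        raise DegenerateInputError(
            "degenerate distance distribution (d_max == d_min)"
        )
    return (d_max - d_min) / bc


def density_ranking(points: PointCloud3, radius_rc: float) -> DensityField:
    """Count neighbors within ``radius_rc`` and rank cells by density.

    Counts use the closed ball (distance <= ``R_c``) and exclude the cell
    itself; ties in the ranking are broken by ascending cell index.
    """
    if radius_rc <= 0:
        raise ValueError("radius_rc must be positive")
    X = points.coords
    nn = NearestNeighbors(radius=radius_rc).fit(X)
    neigh = nn.radius_neighbors(X, return_distance=False)
    counts = np.array([len(ix) - 1 for ix in neigh], dtype=int)
    ranking = np.lexsort((np.arange(len(counts)), -counts))
    return DensityField(radius_rc=radius_rc, neighbor_counts=counts, ranking=ranking)


def _affine_extremes(pts: np.ndarray) -> np.ndarray:
    """Extreme points of a rank-deficient point set (local indices).

    Falls back through the affine-subspace hull: a 2-D hull for coplanar
    sets, segment endpoints for collinear sets, and the full set when all
    points coincide (the group then has no proper hull and its mean
    pairwise member distance plays the role of ``Rbar_H``).
    """
    n = pts.shape[0]
    center = pts.mean(axis=0)
    C = pts - center
    scale = np.abs(C).max()
    if scale == 0:
        return np.arange(n)
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    rank = int((s > 1e-9 * s[0]).sum()) if s[0] > 0 else 0
    if rank <= 0:
        return np.arange(n)
    if rank == 1:
        t = C @ Vt[0]
        lo, hi = int(np.argmin(t)), int(np.argmax(t))
        return np.unique([lo, hi])
    if rank == 2:
        Y = C @ Vt[:2].T
        try:
            return np.asarray(ConvexHull(Y).vertices, dtype=int)
        except QhullError:
            return np.arange(n)
    return np.arange(n)


def _extreme_points(pts: np.ndarray) -> np.ndarray:
    """Indices (into ``pts``) of the convex-hull vertices, degeneracy-safe."""
    n, dim = pts.shape
    if n <= dim:
        return _affine_extremes(pts)
    try:
        return np.asarray(ConvexHull(pts).vertices, dtype=int)
    except QhullError:
        return _affine_extremes(pts)


class _Group:
    """Mutable group state during the ranked scan."""

    __slots__ = ("peak", "members", "vertex_idx", "rbar", "_X")

    def __init__(self, peak: int, member_idx: np.ndarray, X: np.ndarray) -> None:
        self.peak = int(peak)
        self._X = X
        self.members: list[int] = [int(i) for i in member_idx]
        self._rebuild(np.asarray(member_idx, dtype=int))

    def _rebuild(self, candidate_idx: np.ndarray) -> None:
        loc = _extreme_points(self._X[candidate_idx])
        self.vertex_idx = candidate_idx[loc]
        vc = self._X[self.vertex_idx]
        self.rbar = float(pdist(vc).mean()) if len(vc) >= 2 else 0.0

    def dist_to_vertices(self, p: np.ndarray) -> float:
        return float(np.linalg.norm(self._X[self.vertex_idx] - p, axis=1).min())

    def add(self, i: int) -> None:
        # hull(S + p) has vertices within vertices(hull(S)) + p, so the
        # hull update only needs the previous vertex set and the new point
        self.members.append(int(i))
        self._rebuild(np.append(self.vertex_idx, int(i)))


def _first_bin(X: np.ndarray, peak: int, unassigned: np.ndarray, bg: int) -> np.ndarray:
    """Unassigned cells in the first of ``bg`` equal-width distance bins.

    The histogram of distances to the peak spans the whole cloud (its
    range is a property of the data, not of the scan state), so the seed
    is every still-unassigned cell within ``d_max / bg`` of the peak,
    with ``d_max`` the distance from the peak to the farthest cell. The
    peak itself, at distance 0, is always included.
    """
    d_max = np.linalg.norm(X - X[peak], axis=1).max()
    idx = np.flatnonzero(unassigned)
    if d_max == 0:
        return idx
    d = np.linalg.norm(X[idx] - X[peak], axis=1)
    return idx[d <= d_max / bg]


def find_local_maxima(
    points: PointCloud3, field: DensityField, bg: int
) -> list[MaximaGroup]:
    """Discover local density maxima by the ordered convex-hull scan.

    Returns at least one group; groups are pairwise disjoint and each
    contains its peak. See the module docstring for the full procedure.
    """
    X = points.coords
    n, dim = X.shape
    if n < dim + 1:
        raise DegenerateInputError(
            f"need at least {dim + 1} points to build a convex hull in {dim}-D"
        )
    assigned = np.zeros(n, dtype=bool)
    groups: list[_Group] = []
    for m in field.ranking:
        if assigned[m]:
            continue
        best: _Group | None = None
        best_r = np.inf
        for g in groups:
            r = g.dist_to_vertices(X[m])
            if r < g.rbar and r < best_r:
                best, best_r = g, r
        if best is not None:
            assigned[m] = True
            best.add(m)
            continue
        if n - int(assigned.sum()) < dim + 1:
            break  # remainder cannot form a hull; nearest-peak assignment
        seed = _first_bin(X, m, ~assigned, bg)
        if seed.size < dim + 1 and groups:
            # too few cells in the candidate's first bin to construct a
            # convex hull: the search for further local maxima ends
            break
        groups.append(_Group(m, seed, X))
        assigned[seed] = True
    return [
        MaximaGroup(
            peak_index=g.peak,
            member_indices=np.sort(np.array(g.members, dtype=int)),
            hull_vertices=X[g.vertex_idx].copy(),
        )
        for g in groups
    ]


def optimize_bin_size(
    points: PointCloud3, field: DensityField, params: OlmcParams
) -> int:
    """Choose ``bg`` by the saturation heuristic.

    Runs the local-maximum scan for ``bg = bg_step, 2*bg_step, ...`` and
    returns the first bin count at which the number of maxima equals the
    count at the next step (a saturated state), or the ceiling
    ``bg_step * maxbb`` if saturation is never reached. Clouds with at
    least ``cell_number`` points skip the scan and use the default ``bg``.
    """
    if points.n_points >= params.cell_number:
        return params.bg
    bgs = [params.bg_step * k for k in range(1, params.maxbb + 1)]
    counts: list[int] = []
    for b in bgs:
        counts.append(len(find_local_maxima(points, field, b)))
        if len(counts) >= 2 and counts[-1] == counts[-2]:
            return bgs[len(counts) - 2]
    return bgs[-1]


def assign_to_maxima(points: PointCloud3, maxima: list[MaximaGroup]) -> Partition:
    """Assign every cell to the nearest local-maximum peak.

    Cells already absorbed by a group keep that group's label; remaining
    cells take the label of the group whose peak point is nearest
    (Euclidean), ties going to the lowest group label.
    """
    if not maxima:
        raise ValueError("need at least one group")
    X = points.coords
    n = X.shape[0]
    labels = np.full(n, -1, dtype=int)
    for lbl, g in enumerate(maxima):
        labels[g.member_indices] = lbl
    free = np.flatnonzero(labels < 0)
    if free.size:
        peaks = X[[g.peak_index for g in maxima]]
        d = np.linalg.norm(X[free, None, :] - peaks[None, :, :], axis=2)
        labels[free] = d.argmin(axis=1)  # argmin takes the lowest label on ties
    return Partition(
        labels={c: int(l) for c, l in zip(points.cell_ids, labels)},
    )


def olmc_cluster(
    points: PointCloud3,
    params: OlmcParams | None = None,
    *,
    return_details: bool = False,
):
    """Run the full OLMC pipeline on a point cloud.

    Composes radius estimation, density ranking, the bin-size saturation
    scan (when the cloud is below ``cell_number`` points), local-maximum
    discovery and nearest-peak assignment. Deterministic for fixed input.
    Degenerate geometry collapses to a single-cluster partition with a
    logged warning.
    """
    params = params or OlmcParams()
    try:
        rc = neighbor_radius(points, params.bc, convention=params.radius_convention)
        field = density_ranking(points, rc)
        bg = optimize_bin_size(points, field, params)
        maxima = find_local_maxima(points, field, bg)
    except DegenerateInputError as exc:
        logger.warning("OLMC degenerate geometry (%s); returning one cluster", exc)
        part = Partition(labels={c: 0 for c in points.cell_ids})
        if return_details:
            return part, OlmcDetails(radius_rc=float("nan"), bg_used=0, n_maxima=1)
        return part
    part = assign_to_maxima(points, maxima)
    if return_details:
        return part, OlmcDetails(radius_rc=rc, bg_used=bg, n_maxima=len(maxima))
    return part
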