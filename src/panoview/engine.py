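"""The iterative outer loop: variable genes -> 3-D PCA -> OLMC -> maturity.

Each iteration re-selects variable genes on the cells still in play, embeds
them in a fresh 3-D PCA space, clusters with OLMC, and evaluates cluster
tightness as the variance of within-cluster pairwise correlation distances
in the current (variable-gene) space. The Gini index of the cluster-variance
profile gates the loop: while some prefix of the variance ranking is unequal
enough (any ``G_i`` above the threshold), the tightest ("mature") cluster is
frozen, its cells are removed, and the loop repeats on the remainder; once
all ``G_i`` fall below the threshold the surviving clusters join the frozen
ones as the output. A final average-linkage dendrogram over cluster
centroids (correlation distance) merges clusters joined below a fraction of
the maximum merge height.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .embed import pca3
from .exceptions import DegenerateInputError, UndefinedDistanceError
from .genes import VariableGeneParams, select_variable_genes
from .matrix_io import ExpressionMatrix
from .olmc import OlmcParams, olmc_cluster
from .partition import Partition

__all__ = [
    "PanoViewParams",
    "IterationRecord",
    "MatureDecision",
    "correlation_distance",
    "gini_index",
    "select_mature",
    "run_panoview",
    "merge_clusters",
    "cluster_cells",
]

logger = logging.getLogger("panoview")


@dataclass(frozen=True)
class PanoViewParams:
    """The eight user-facing knobs of the pipeline, at their defaults.

    zscore_cut, gene_low
        Variable-gene selection (1.5 and 0.5).
    gini_threshold
        Gini gate on the cluster-variance profile (0.05); equality at the
        threshold counts as below (stop).
    bc, bg, maxbb, cell_number
        OLMC knobs (20, 20, 20, 1000).
    fclust_height
        Dendrogram merge threshold as a fraction of the maximum merge
        height (0.20, i.e. "differential cluster-cluster distance < 20%").

    The keyword-only fields are recorded dialect switches: ``log1p``
    transforms values before dispersion computation, ``scale_genes``
    standardizes genes before PCA, ``radius_convention`` picks the R_c
    formula, and ``variance_space`` chooses the gene space in which cluster
    variances are evaluated (``"variable"``, the current variable-gene
    submatrix, or ``"full"``).
    """

    zscore_cut: float = 1.5
    gene_low: float = 0.5
    gini_threshold: float = 0.05
    bc: int = 20
    bg: int = 20
    maxbb: int = 20
    cell_number: int = 1000
    fclust_height: float = 0.20
    log1p: bool = False
    scale_genes: str = "none"
    radius_convention: str = "range"
    variance_space: str = "variable"

    def __post_init__(self) -> None:
        if not 0 < self.gini_threshold < 1:
            raise ValueError("gini_threshold must be in (0, 1)")
        if not 0 < self.fclust_height <= 1:
            raise ValueError("fclust_height must be in (0, 1]")
        if self.variance_space not in ("variable", "full"):
            raise ValueError("variance_space must be 'variable' or 'full'")

    def gene_params(self) -> VariableGeneParams:
        return VariableGeneParams(
            zscore_cut=self.zscore_cut, gene_low=self.gene_low, log1p=self.log1p
        )

    def olmc_params(self) -> OlmcParams:
        return OlmcParams(
            bc=self.bc,
            bg=self.bg,
            maxbb=self.maxbb,
            cell_number=self.cell_number,
            radius_convention=self.radius_convention,
        )


@dataclass(frozen=True)
class IterationRecord:
    """One line of the run log."""

    iteration: int
    n_cells: int
    n_variable_genes: int
    n_clusters: int
    bg_used: int
    mature_label: int | None
    mature_size: int | None
    gini_values: tuple[float, ...]


@dataclass(frozen=True)
class MatureDecision:
    """Outcome of the Gini evaluation of one iteration's clusters."""

    stop: bool
    mature_label: int | None
    residual_labels: tuple[int, ...]
    variances: dict[int, float]
    gini_values: tuple[float, ...]


def correlation_distance(v, w) -> float:
    """1 minus the Pearson correlation of two expression vectors, in [0, 2]."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or v.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    vc = v - v.mean()
    wc = w - w.mean()
    nv = np.linalg.norm(vc)
    nw = np.linalg.norm(wc)
    if nv == 0 or nw == 0:
        raise UndefinedDistanceError("correlation undefined for a constant vector")
    return float(np.clip(1.0 - vc @ wc / (nv * nw), 0.0, 2.0))


def gini_index(variances) -> float:
    """Gini index of a set of cluster variances.

    ``G = sum_ij |s_i - s_j| / (2 n^2 mu)``, in [0, 1). All-zero input
    (mu = 0) is defined as 0, perfect equality.
    """
    x = np.asarray(variances, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two variances")
    if np.any(x < 0):
        raise ValueError("variances must be nonnegative")
    mu = x.mean()
    if mu == 0:
        logger.debug("gini_index of all-zero variances; returning 0")
        return 0.0
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * mu))


def _pairwise_correlation_distances(X: np.ndarray) -> np.ndarray:
    """Condensed correlation distances among rows; constant rows -> 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = pdist(X, metric="correlation")
    bad = ~np.isfinite(d)
    if bad.any():
        logger.debug(
            "substituting distance 1 for %d undefined correlation pairs", bad.sum()
        )
        d = np.where(bad, 1.0, d)
    return np.clip(d, 0.0, 2.0)


def _cluster_variances(E: ExpressionMatrix, partition: Partition) -> dict[int, float]:
    """Variance of within-cluster pairwise correlation distances per label.

    Clusters with fewer than 3 members have at most one pairwise distance,
    so their variance is trivially zero and carries no information about
    tightness; it is reported as NaN and such clusters do not compete for
    maturity (they stay in play until the stop iteration, where the final
    dendrogram merge reabsorbs genuine fragments).
    """
    cells = E.cell_ids
    pos = {c: i for i, c in enumerate(cells)}
    Xc = E.values.T  # cells x genes
    out: dict[int, float] = {}
    for lbl in partition.cluster_labels:
        members = [pos[c] for c in partition.members(lbl)]
        if len(members) < 3:
            logger.debug("cluster %d has %d members; variance undefined",
                         lbl, len(members))
            out[lbl] = float("nan")
            continue
        d = _pairwise_correlation_distances(Xc[members])
        out[lbl] = float(d.var())
    return out


def select_mature(
    E: ExpressionMatrix, clusters: Partition, gini_threshold: float = 0.05
) -> MatureDecision:
    """Decide whether this iteration freezes a mature cluster or stops.

    Clusters are ranked by variance (of within-cluster correlation
    distances over the genes of ``E``) in descending order, and the Gini
    index ``G_i`` is computed for the top-``i`` variances, ``i = 2..n``. If
    any ``G_i`` exceeds the threshold, the minimum-variance cluster is
    declared mature (ties by smallest label) and iteration continues;
    if all ``G_i`` are at or below the threshold — or at most one cluster
    has a defined variance — the iteration stops. Clusters with fewer
    than 3 members have no defined variance and do not compete for
    maturity (the closing dendrogram merge deals with such fragments).
    """
    variances = _cluster_variances(E, clusters)
    labels = sorted(variances)
    eligible = [l for l in labels if np.isfinite(variances[l])]
    if len(eligible) <= 1:
        return MatureDecision(True, None, tuple(labels), variances, ())
    order = sorted(eligible, key=lambda l: (-variances[l], l))
    ranked = np.array([variances[l] for l in order])
    ginis = tuple(gini_index(ranked[:i]) for i in range(2, len(order) + 1))
    if any(g > gini_threshold for g in ginis):
        mature = min(eligible, key=lambda l: (variances[l], l))
        residual = tuple(l for l in labels if l != mature)
        return MatureDecision(False, mature, residual, variances, ginis)
    return MatureDecision(True, None, tuple(labels), variances, ginis)


def run_panoview(
    E: ExpressionMatrix, params: PanoViewParams | None = None
) -> tuple[Partition, list[IterationRecord]]:
    """Run the iterative search, returning the pre-merge partition and log.

    The loop terminates because every continued iteration removes at least
    one cell; a residue with fewer than 4 cells, or without enough variable
    genes to embed, becomes one terminal cluster.
    """
    params = params or PanoViewParams()
    if E.n_cells < 4:
        raise DegenerateInputError("need at least 4 cells")
    gene_params = params.gene_params()
    olmc_params = params.olmc_params()

    remaining = np.arange(E.n_cells)
    frozen: list[tuple[np.ndarray, int]] = []  # (global cell indices, iteration)
    trace: list[IterationRecord] = []
    final_sets: list[np.ndarray] = []
    iteration = 1
    while True:
        if remaining.size < 4:
            logger.info("iteration %d: residue of %d cells becomes one terminal cluster",
                        iteration, remaining.size)
            final_sets = [remaining]
            break
        E_i = E.subset_cells(remaining)
        vg = select_variable_genes(E_i, gene_params)
        if vg.size < 3:
            logger.info("iteration %d: %d variable genes left; stopping",
                        iteration, vg.size)
            final_sets = [remaining]
            break
        points = pca3(E_i, vg, scale_genes=params.scale_genes)
        part, details = olmc_cluster(points, olmc_params, return_details=True)
        E_eval = E_i.subset_genes(vg) if params.variance_space == "variable" else E_i
        decision = select_mature(E_eval, part, params.gini_threshold)
        local_members = {
            lbl: np.array([E_i.cell_ids.index(c) for c in part.members(lbl)])
            for lbl in part.cluster_labels
        }
        mature_size = (
            local_members[decision.mature_label].size
            if decision.mature_label is not None
            else None
        )
        trace.append(
            IterationRecord(
                iteration=iteration,
                n_cells=remaining.size,
                n_variable_genes=int(vg.size),
                n_clusters=part.n_clusters,
                bg_used=details.bg_used,
                mature_label=decision.mature_label,
                mature_size=mature_size,
                gini_values=decision.gini_values,
            )
        )
        if decision.stop:
            final_sets = [remaining[local_members[l]] for l in sorted(local_members)]
            break
        mature_global = remaining[local_members[decision.mature_label]]
        frozen.append((mature_global, iteration))
        keep = np.setdiff1d(
            np.arange(remaining.size), local_members[decision.mature_label]
        )
        remaining = remaining[keep]
        iteration += 1

    labels: dict[str, int] = {}
    iteration_found: dict[int, int] = {}
    next_label = 0
    for cells, it in frozen:
        for i in cells:
            labels[E.cell_ids[i]] = next_label
        iteration_found[next_label] = it
        next_label += 1
    for cells in final_sets:
        if cells.size == 0:
            continue
        for i in cells:
            labels[E.cell_ids[i]] = next_label
        iteration_found[next_label] = iteration
        next_label += 1
    return Partition(labels=labels, iteration_found=iteration_found), trace


def merge_clusters(
    E: ExpressionMatrix, M: Partition, fclust_height: float = 0.20
) -> Partition:
    """Merge similar clusters on a centroid dendrogram.

    Centroids are mean expression profiles over the genes of ``E``;
    the dendrogram uses correlation distance with average linkage, and
    clusters joined below ``fclust_height`` times the maximum merge height
    are flattened together. A single-cluster partition is returned
    unchanged. Merged labels take the smallest constituent label, so a
    merge-free call is the identity on labels.
    """
    old_labels = M.cluster_labels
    if len(old_labels) == 1:
        return Partition(
            labels=dict(M.labels),
            iteration_found=dict(M.iteration_found),
            merged_from={old_labels[0]: (old_labels[0],)},
        )
    centroids = np.vstack(
        [
            np.mean(
                [E.values[:, E.cell_ids.index(c)] for c in M.members(l)], axis=0
            )
            for l in old_labels
        ]
    )
    d = _pairwise_correlation_distances(centroids)
    Z = linkage(d, method="average")
    max_height = float(Z[:, 2].max())
    groups = fcluster(Z, t=fclust_height * max_height, criterion="distance")
    new_of_old: dict[int, int] = {}
    merged_from: dict[int, tuple[int, ...]] = {}
    for gid in np.unique(groups):
        olds = tuple(old_labels[i] for i in np.flatnonzero(groups == gid))
        new = min(olds)
        merged_from[new] = olds
        for o in olds:
            new_of_old[o] = new
    labels = {c: new_of_old[l] for c, l in M.labels.items()}
    iteration_found = {
        new: min(M.iteration_found.get(o, 1) for o in olds)
        for new, olds in merged_from.items()
    }
    return Partition(
        labels=labels, iteration_found=iteration_found, merged_from=merged_from
    )


def cluster_cells(
    E: ExpressionMatrix, params: PanoViewParams | None = None
) -> tuple[Partition, list[IterationRecord]]:
    """Full pipeline: iterative search followed by the dendrogram merge."""
    params = params or PanoViewParams()
    part, trace = run_panoview(E, params)
    merged = merge_clusters(E, part, params.fclust_height)
    return merged, trace
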