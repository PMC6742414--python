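"""OLMC: radius estimation, density ranking, hull scan, assignment."""

import numpy as np
import pytest

import panoview.olmc as olmc_mod
from panoview import (
    OlmcParams,
    adjusted_rand_index,
    assign_to_maxima,
    density_ranking,
    find_local_maxima,
    neighbor_radius,
    olmc_cluster,
    optimize_bin_size,
)
from panoview.exceptions import DegenerateInputError

from conftest import gaussian_modes, make_cloud


def brute_counts(X, r):
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    return ((d <= r).sum(axis=1) - 1).astype(int)


class TestNeighborRadius:
    def test_collinear_points_bin_interval(self):
        pts = make_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        # pairwise distances {1, 1, 2}: (2 - 1) / 20
        assert neighbor_radius(pts, 20) == pytest.approx(0.05)

    def test_two_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            neighbor_radius(make_cloud([[0, 0, 0], [3, 0, 0]]), 20)

    def test_all_coincident_degenerate(self):
        with pytest.raises(DegenerateInputError):
            neighbor_radius(make_cloud([[1, 1, 1]] * 5), 20)

    def test_homogeneous_under_scaling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        r1 = neighbor_radius(make_cloud(X), 20)
        r2 = neighbor_radius(make_cloud(3.7 * X), 20)
        assert r2 == pytest.approx(3.7 * r1)

    def test_max_dialect(self):
        pts = make_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert neighbor_radius(pts, 20, convention="max") == pytest.approx(0.1)


class TestDensityRanking:
    def test_three_collinear_counts_and_global_maximum(self):
        pts = make_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        field = density_ranking(pts, 1.1)
        assert field.neighbor_counts.tolist() == [1, 2, 1]
        assert field.ranking[0] == 1  # the middle point is P_1

    def test_radius_below_all_distances_gives_zero_counts(self):
        pts = make_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert density_ranking(pts, 0.5).neighbor_counts.tolist() == [0, 0, 0]

    @pytest.mark.parametrize("dim", [2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force(self, dim, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, dim))
        pts = make_cloud(X)
        r = neighbor_radius(pts, 20)
        field = density_ranking(pts, r)
        np.testing.assert_array_equal(field.neighbor_counts, brute_counts(X, r))

    def test_ties_broken_by_ascending_index(self):
        pts = make_cloud([[0, 0, 0], [1, 0, 0], [10, 0, 0], [11, 0, 0]])
        field = density_ranking(pts, 1.5)  # all counts equal 1
        assert field.ranking.tolist() == [0, 1, 2, 3]


class TestFindLocalMaxima:
    @pytest.mark.parametrize("dim", [2, 3])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_well_separated_modes_yield_exactly_k_groups(self, dim, k):
        centers = 20.0 * np.eye(max(k, dim))[:k, :dim]
        pts, labels = gaussian_modes(centers, n_per_mode=50, sd=1.0, seed=5)
        field = density_ranking(pts, neighbor_radius(pts, 20))
        bg = optimize_bin_size(pts, field, OlmcParams())
        groups = find_local_maxima(pts, field, bg)
        assert len(groups) == k
        # each peak is the densest cell of its own mode (brute-force check)
        counts = field.neighbor_counts
        for g in groups:
            mode = labels[g.peak_index]
            assert counts[g.peak_index] == counts[labels == mode].max()

    def test_groups_disjoint_and_contain_their_peak(self):
        pts, _ = gaussian_modes([[0, 0, 0], [25, 0, 0]], 40, 1.0, seed=7)
        field = density_ranking(pts, neighbor_radius(pts, 20))
        groups = find_local_maxima(pts, field, bg=10)
        seen = set()
        for g in groups:
            members = set(g.member_indices.tolist())
            assert g.peak_index in members
            assert not (members & seen)
            seen |= members

    def test_tetrahedron_with_distant_singleton_gives_one_group(self):
        tetra = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        pts = make_cloud(np.vstack([tetra, [[50, 50, 50]]]))
        field = density_ranking(pts, 1.2)
        groups = find_local_maxima(pts, field, bg=10)
        assert len(groups) == 1
        assert 4 not in groups[0].member_indices  # singleton left unassigned

    def test_seed_bin_points_lie_in_initial_hull(self):
        # independent hull-membership check: every seeding cell is inside
        # (or on) the convex hull spanned by the reported vertices
        from scipy.optimize import linprog

        pts, _ = gaussian_modes([[0, 0, 0]], 40, 1.0, seed=11)
        field = density_ranking(pts, neighbor_radius(pts, 20))
        g = find_local_maxima(pts, field, bg=5)[0]
        V = g.hull_vertices
        for idx in g.member_indices[:10]:
            p = pts.coords[idx]
            # p is a convex combination of vertices <=> LP feasible
            res = linprog(
                c=np.zeros(len(V)),
                A_eq=np.vstack([V.T, np.ones(len(V))]),
                b_eq=np.append(p, 1.0),
                bounds=[(0, None)] * len(V),
                method="highs",
            )
            if not res.success:
                # members absorbed later during the scan may legally lie
                # outside the final hull only if they are hull vertices
                assert any(np.allclose(p, v) for v in V)


class TestAssignToMaxima:
    def test_single_group_labels_everyone(self):
        pts, _ = gaussian_modes([[0, 0, 0]], 30, 1.0, seed=3)
        field = density_ranking(pts, neighbor_radius(pts, 20))
        groups = find_local_maxima(pts, field, bg=10)
        part = assign_to_maxima(pts, groups)
        assert part.n_cells == 30

    def test_matches_brute_force_nearest_peak(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        pts = make_cloud(X)
        field = density_ranking(pts, neighbor_radius(pts, 20))
        groups = find_local_maxima(pts, field, bg=10)
        part = assign_to_maxima(pts, groups)
        labels = part.labels_for(pts.cell_ids)
        member_of = {}
        for lbl, g in enumerate(groups):
            for i in g.member_indices:
                member_of[int(i)] = lbl
        peaks = np.array([X[g.peak_index] for g in groups])
        for i in range(50):
            if i in member_of:
                assert labels[i] == member_of[i]
            else:
                d = np.linalg.norm(peaks - X[i], axis=1)
                assert labels[i] == d.argmin()

    def test_equidistant_cell_goes_to_lower_label(self):
        # two tight triangles as groups; one cell exactly between the peaks
        X = np.array(
            [
                [0, 0], [0.1, 0], [0, 0.1],
                [10, 0], [9.9, 0], [10, 0.1],
                [5, 0],
            ],
            dtype=float,
        )
        pts = make_cloud(X)
        field = density_ranking(pts, 0.2)
        groups = find_local_maxima(pts, field, bg=50)
        assert len(groups) == 2
        part = assign_to_maxima(pts, groups)
        labels = part.labels_for(pts.cell_ids)
        d0 = np.linalg.norm(X[6] - X[groups[0].peak_index])
        d1 = np.linalg.norm(X[6] - X[groups[1].peak_index])
        assert d0 == d1
        assert labels[6] == 0


class TestOptimizeBinSize:
    def test_large_clouds_skip_the_scan(self):
        rng = np.random.default_rng(1)
        pts = make_cloud(rng.normal(size=(30, 3)))
        field = density_ranking(pts, neighbor_radius(pts, 20))
        params = OlmcParams(cell_number=10, bg=20)
        assert optimize_bin_size(pts, field, params) == 20

    def test_first_plateau_wins(self, monkeypatch):
        counts = {5: 1, 10: 2, 15: 3, 20: 3, 25: 3}
        monkeypatch.setattr(
            olmc_mod,
            "find_local_maxima",
            lambda pts, field, bg: [None] * counts.get(bg, 99),
        )
        pts = make_cloud(np.random.default_rng(0).normal(size=(20, 3)))
        field = density_ranking(pts, 1.0)
        assert optimize_bin_size(pts, field, OlmcParams()) == 15

    def test_never_saturating_returns_ceiling(self, monkeypatch):
        monkeypatch.setattr(
            olmc_mod,
            "find_local_maxima",
            lambda pts, field, bg: [None] * bg,  # strictly increasing
        )
        pts = make_cloud(np.random.default_rng(0).normal(size=(20, 3)))
        field = density_ranking(pts, 1.0)
        assert optimize_bin_size(pts, field, OlmcParams()) == 100


class TestOlmcCluster:
    def test_three_separated_blobs_perfect_ari(self):
        pts, labels = gaussian_modes(
            [[0, 0, 0], [30, 0, 0], [0, 30, 0]], 40, sd=1.0, seed=13
        )
        part = olmc_cluster(pts)
        assert part.n_clusters == 3
        assert adjusted_rand_index(labels, part.labels_for(pts.cell_ids)) == 1.0

    def test_single_blob_single_cluster(self):
        pts, _ = gaussian_modes([[0, 0, 0]], 60, sd=1.0, seed=17)
        part = olmc_cluster(pts)
        assert part.n_clusters == 1

    def test_partition_exhaustive_and_disjoint(self):
        pts, _ = gaussian_modes([[0, 0, 0], [25, 0, 0]], 45, 1.0, seed=19)
        part = olmc_cluster(pts)
        assert sorted(part.labels) == sorted(pts.cell_ids)

    def test_rigid_motion_leaves_partition_unchanged(self):
        pts, _ = gaussian_modes([[0, 0, 0], [25, 0, 0]], 40, 1.0, seed=23)
        base = olmc_cluster(pts).labels_for(pts.cell_ids)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = make_cloud(pts.coords @ R.T + np.array([5.0, -3.0, 2.0]))
        rotated = olmc_cluster(moved).labels_for(moved.cell_ids)
        assert adjusted_rand_index(base, rotated) == 1.0

    def test_pc_sign_flip_invariance(self):
        pts, _ = gaussian_modes([[0, 0, 0], [25, 0, 0]], 40, 1.0, seed=29)
        base = olmc_cluster(pts).labels_for(pts.cell_ids)
        flipped = make_cloud(pts.coords * np.array([-1.0, 1.0, -1.0]))
        assert adjusted_rand_index(
            base, olmc_cluster(flipped).labels_for(flipped.cell_ids)
        ) == 1.0

    def test_coincident_points_collapse_to_one_cluster_with_warning(self, caplog):
        pts = make_cloud([[1.0, 1.0, 1.0]] * 6)
        with caplog.at_level("WARNING", logger="panoview"):
            part = olmc_cluster(pts)
        assert part.n_clusters == 1
        assert any("degenerate" in r.message for r in caplog.records)
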