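"""Landscape averaging, basin finding, extraction, clustering, occupancy."""

import numpy as np
import pytest

from conftest import dbscan_bruteforce, labels_equivalent
from mabp import (
    BasinRegion,
    FESLandscape,
    Trajectory,
    average_landscapes,
    basin_occupancy,
    cluster_poses,
    extract_frames,
    find_minima,
)
from mabp.analysis import pose_rmsd_matrix


def fes_1d(F, lo=0.0, hi=10.0, periodic=False, visited=None):
    F = np.asarray(F, dtype=float)
    if visited is None:
        visited = np.ones_like(F, dtype=bool)
    return FESLandscape(
        bins=(len(F),), lo=(lo,), hi=(hi,), periodic=(periodic,),
        F=np.where(visited, F, np.nan), visited=visited,
    )


class TestAverage:
    def test_single_input_identity(self):
        a = fes_1d([0.0, 1.0, 2.0, 0.5])
        out = average_landscapes([a])
        assert np.allclose(out.F, a.F)

    def test_cellwise_mean_with_shift(self):
        a = fes_1d([0.0, 2.0])
        b = fes_1d([2.0, 0.0])
        out = average_landscapes([a, b])
        assert np.allclose(out.F, [0.0, 0.0])  # mean is 1 everywhere, re-shifted
        c = fes_1d([0.0, 4.0])
        out2 = average_landscapes([a, c])
        assert np.allclose(out2.F, [0.0, 3.0])

    def test_visited_union_and_partial_cells(self):
        a = fes_1d([0.0, 1.0, np.nan], visited=np.array([True, True, False]))
        b = fes_1d([np.nan, 3.0, 2.0], visited=np.array([False, True, True]))
        out = average_landscapes([a, b])
        assert out.visited.all()
        assert np.allclose(out.F, [0.0, 2.0, 2.0])
        assert out.replicate_count == 2

    def test_geometry_mismatch_rejected(self):
        a = fes_1d([0.0, 1.0])
        b = fes_1d([0.0, 1.0], hi=20.0)
        with pytest.raises(ValueError, match="geometry"):
            average_landscapes([a, b])


class TestFindMinima:
    def test_single_well(self):
        x = np.linspace(0, 10, 50)
        fes = fes_1d(0.5 * (x - 5.0) ** 2)
        basins = find_minima(fes, depth_threshold=1.0)
        assert len(basins) == 1
        assert basins[0].lo[0] < 5.0 < basins[0].hi[0]

    def test_symmetric_double_well_equal_depths(self):
        x = np.linspace(-2, 2, 81)
        fes = fes_1d(2.0 * (x**2 - 1) ** 2, lo=-2, hi=2)
        basins = find_minima(fes, depth_threshold=1.0)
        assert len(basins) == 2
        depth = [
            fes.F[int((0.5 * (b.lo[0] + b.hi[0]) - fes.lo[0]) / fes.bin_widths[0])]
            for b in basins
        ]
        assert abs(depth[0] - depth[1]) < 1e-9

    def test_planted_three_minima_2d(self):
        bins = 60
        c = np.linspace(0.05, 9.95, bins)
        X, Y = np.meshgrid(c, c, indexing="ij")
        centers = [(2.0, 2.0), (5.0, 7.0), (8.0, 3.0)]
        F = np.full((bins, bins), 6.0)
        for cx, cy in centers:
            F -= 5.0 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.6**2))
        F -= F.min()
        fes = FESLandscape(
            bins=(bins, bins), lo=(0, 0), hi=(10, 10),
            periodic=(False, False), F=F,
            visited=np.ones((bins, bins), dtype=bool),
        )
        basins = find_minima(fes, depth_threshold=3.0)
        assert len(basins) == 3
        for cx, cy in centers:
            assert any(
                b.lo[0] <= cx <= b.hi[0] and b.lo[1] <= cy <= b.hi[1]
                for b in basins
            )

    def test_periodic_wrap_minimum_at_edge(self):
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False) + np.pi / 120
        fes = fes_1d(2 * (1 - np.cos(theta)), hi=2 * np.pi, periodic=True)
        basins = find_minima(fes, depth_threshold=1.0)
        assert len(basins) == 1  # single well at theta = 0 (wrapped edge)


class TestExtract:
    def _traj(self, cv):
        cv = np.asarray(cv, dtype=float)
        n = len(cv)
        frames = np.zeros((n, 3, 3))
        frames[:, 0, 0] = np.arange(n)  # identifiable frames
        return Trajectory(
            frames=frames, cv_trace=cv, times=np.arange(n, dtype=float),
            stride=1, metadata={},
        )

    def test_full_region_returns_all(self):
        traj = self._traj(np.column_stack([np.linspace(0, 9, 10)] * 2))
        region = BasinRegion(lo=(0.0, 0.0), hi=(10.0, 10.0))
        idx, frames = extract_frames(traj, region)
        assert len(idx) == 10

    def test_planted_membership_counts(self, rng):
        cv = rng.uniform(0, 10, size=(200, 2))
        region = BasinRegion(lo=(2.0, 3.0), hi=(5.0, 6.0))
        expected = np.nonzero(region.contains(cv))[0]
        traj = self._traj(cv)
        idx, _ = extract_frames(traj, region)
        assert np.array_equal(idx, expected)
        # complement partitions the trajectory exactly
        outside = np.setdiff1d(np.arange(200), idx)
        assert len(idx) + len(outside) == 200

    def test_ligand_subset(self):
        traj = self._traj(np.zeros((5, 2)))
        region = BasinRegion(lo=(-1.0, -1.0), hi=(1.0, 1.0))
        _, frames = extract_frames(traj, region, ligand_indices=[1, 2])
        assert frames.shape == (5, 2, 3)

    def test_empty_overlap_warns(self):
        traj = self._traj(np.zeros((5, 2)))
        region = BasinRegion(lo=(8.0, 8.0), hi=(9.0, 9.0))
        with pytest.warns(UserWarning, match="no frames"):
            idx, frames = extract_frames(traj, region)
        assert len(idx) == 0


class TestClusterPoses:
    def _blob(self, rng, center, n, sigma=0.1):
        base = np.zeros((4, 3))
        base[:, 0] = np.arange(4) * 1.5
        return base + np.asarray(center) + rng.normal(0, sigma, size=(n, 4, 3))

    def test_identical_frames_single_cluster(self):
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (30, 1, 1))
        res = cluster_poses(frames)
        assert res.n_clusters == 1
        assert np.all(res.labels == 0)
        assert res.representative is not None

    def test_below_min_pts_all_noise(self):
        # 24 identical frames < min_pts = 25
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (24, 1, 1))
        res = cluster_poses(frames)
        assert res.n_clusters == 0
        assert np.all(res.labels == -1)
        assert res.representative is None

    def test_planted_blobs_match_bruteforce_oracle(self, rng):
        a = self._blob(rng, [0, 0, 0], 100)
        b = self._blob(rng, [0, 5.0, 0], 100)
        frames = np.concatenate([a, b])
        perm = rng.permutation(200)
        frames = frames[perm]
        res = cluster_poses(frames, eps=0.7, min_pts=25)
        assert res.n_clusters == 2
        oracle = dbscan_bruteforce(pose_rmsd_matrix(frames), 0.7, 25)
        assert labels_equivalent(res.labels, oracle)

    def test_medoid_minimizes_summed_distance(self, rng):
        frames = self._blob(rng, [0, 0, 0], 40)
        res = cluster_poses(frames)
        D = pose_rmsd_matrix(frames)
        members = np.nonzero(res.labels == 0)[0]
        sums = D[np.ix_(members, members)].sum(axis=1)
        assert res.representative == members[np.argmin(sums)]

    def test_no_refit_metric_is_plain_rmsd(self, rng):
        frames = rng.normal(size=(3, 5, 3))
        D = pose_rmsd_matrix(frames)
        expect = np.sqrt(np.mean(np.sum((frames[0] - frames[1]) ** 2, axis=1)))
        assert np.isclose(D[0, 1], expect)


class TestOccupancy:
    def _cosine_fes(self, bins=300, h=2.0):
        w = 2 * np.pi / bins
        theta = (np.arange(bins) + 0.5) * w
        F = h * (1 - np.cos(theta))
        return fes_1d(F - F.min(), hi=2 * np.pi, periodic=True), theta, w

    def test_flat_landscape_quarter_basin(self):
        fes = fes_1d(np.zeros(100), hi=2 * np.pi, periodic=True)
        occ = basin_occupancy(fes, BasinRegion(lo=(0.0,), hi=(np.pi / 2,)), 0.6)
        assert np.isclose(occ, 0.25)

    def test_deep_well_dominates(self):
        F = np.full(20, 10 * 0.6)
        F[5] = 0.0
        fes = fes_1d(F, hi=2 * np.pi, periodic=True)
        occ = basin_occupancy(
            fes, BasinRegion(lo=(np.pi / 4,), hi=(3 * np.pi / 4,)), 0.6
        )
        assert occ > 0.999

    def test_cosine_profile_matches_quadrature(self):
        # F(theta) = 2(1 - cos theta), basin [-pi/2, pi/2], kT = 0.6
        from scipy.integrate import quad

        fes, _, _ = self._cosine_fes()
        occ = basin_occupancy(
            fes, BasinRegion(lo=(-np.pi / 2,), hi=(np.pi / 2,)), 0.6
        )
        f = lambda t: np.exp(-2 * (1 - np.cos(t)) / 0.6)
        num, _ = quad(f, -np.pi / 2, np.pi / 2)
        den, _ = quad(f, 0.0, 2 * np.pi)
        assert abs(occ - num / den) / (num / den) < 1e-3

    def test_partition_sums_to_one(self):
        fes, _, _ = self._cosine_fes()
        cuts = [0.0, 1.1, 2.0, 4.5, 2 * np.pi]
        occ = sum(
            basin_occupancy(fes, BasinRegion(lo=(a,), hi=(b,)), 0.6)
            for a, b in zip(cuts[:-1], cuts[1:])
        )
        assert abs(occ - 1.0) < 1e-12

    def test_wrapping_basin(self):
        fes, _, _ = self._cosine_fes()
        occ_wrap = basin_occupancy(
            fes, BasinRegion(lo=(3 * np.pi / 2,), hi=(np.pi / 2,)), 0.6
        )
        occ_sym = basin_occupancy(
            fes, BasinRegion(lo=(-np.pi / 2,), hi=(np.pi / 2,)), 0.6
        )
        assert np.isclose(occ_wrap, occ_sym)

    def test_unvisited_cell_in_basin_raises(self):
        visited = np.ones(100, dtype=bool)
        visited[10] = False
        fes = fes_1d(np.zeros(100), hi=2 * np.pi, periodic=True, visited=visited)
        basin = BasinRegion(lo=(0.0,), hi=(np.pi,))
        with pytest.raises(ValueError, match="unvisited"):
            basin_occupancy(fes, basin, 0.6)

    def test_requires_1d(self):
        fes2 = FESLandscape(
            bins=(4, 4), lo=(0, 0), hi=(1, 1), periodic=(False, False),
            F=np.zeros((4, 4)), visited=np.ones((4, 4), dtype=bool),
        )
        with pytest.raises(ValueError, match="1D"):
            basin_occupancy(fes2, BasinRegion(lo=(0.0,), hi=(0.5,)), 0.6)
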