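"""Embedded point cloud and Rips persistence: examples, invariants, oracle."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import statescape as ss
from statescape.epc import PointCloud, maxmin_landmarks
from statescape.segment import RecordingSegment
from statescape.tda import PersistenceInterval, default_grid

from oracles import brute_force_persistence, diagram_to_tuples


class TestBuildEPC:
    def test_columns_become_points(self, rng):
        data = rng.standard_normal((3, 5))
        cloud = ss.build_epc(RecordingSegment(data, 100.0))
        assert cloud.points.shape == (5, 3)
        np.testing.assert_array_equal(cloud.points[2], data[:, 2])

    def test_single_channel_cosine_rejected(self):
        with pytest.raises(ValueError, match="C < 2"):
            ss.build_epc(RecordingSegment(np.ones((1, 10)) * np.arange(10), 100.0))


class TestStateVelocity:
    def test_identical_orthogonal_antiparallel(self):
        pts = np.array([[1, 0], [1, 0], [0, 1], [0, -1]], float)
        v = ss.state_velocity(PointCloud(pts))
        np.testing.assert_allclose(v, [0.0, 1.0, 2.0], atol=1e-12)

    def test_zero_norm_state_flagged_as_nan(self):
        pts = np.array([[1, 0], [0, 0], [0, 1]], float)
        with pytest.warns(UserWarning, match="zero-norm"):
            v = ss.state_velocity(PointCloud(pts))
        assert np.isnan(v).all()


class TestPairwiseDissimilarity:
    def test_orthogonal_unit_vectors(self):
        dm = ss.pairwise_dissimilarity(PointCloud(np.eye(2)))
        np.testing.assert_allclose(dm, [[0, 1], [1, 0]], atol=1e-12)

    def test_cosine_bound_and_diagonal(self, rng):
        dm = ss.pairwise_dissimilarity(PointCloud(rng.standard_normal((40, 5))))
        assert dm.max() <= 2.0 + 1e-12
        assert np.all(np.diag(dm) == 0)
        np.testing.assert_allclose(dm, dm.T)

    def test_repeated_vector_gives_zero_matrix(self):
        pts = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert np.allclose(ss.pairwise_dissimilarity(PointCloud(pts)), 0.0)

    def test_zero_norm_point_rejected_with_index(self):
        pts = np.array([[1, 0], [0, 0]], float)
        with pytest.raises(ValueError, match=r"\[1\]"):
            ss.pairwise_dissimilarity(PointCloud(pts))


class TestMaxminLandmarks:
    def test_covers_small_cloud_entirely(self, rng):
        dm = squareform(pdist(rng.standard_normal((10, 2))))
        assert np.array_equal(maxmin_landmarks(dm, 20), np.arange(10))

    def test_deterministic_and_spread(self):
        pts = ss.gen_circle_cloud(60, 1.0, 0.0)
        dm = squareform(pdist(pts))
        idx1 = maxmin_landmarks(dm, 12)
        idx2 = maxmin_landmarks(dm, 12)
        assert np.array_equal(idx1, idx2)
        # farthest-point landmarks on a circle are nearly equally spaced
        gaps = np.diff(np.sort(idx1 * (2 * np.pi / 60)))
        assert gaps.max() < 3 * (2 * np.pi / 12)


class TestRipsPersistence:
    def test_two_points(self):
        dm = np.array([[0.0, 1.0], [1.0, 0.0]])
        diag = ss.rips_persistence(dm, max_radius=2.0)
        assert diagram_to_tuples(diag) == [(0, 0.0, 1.0), (0, 0.0, np.inf)]

    def test_three_collinear_points_h0_deaths(self):
        x = np.array([[0.0], [1.0], [3.0]])
        dm = squareform(pdist(x))
        diag = ss.rips_persistence(dm, max_radius=10.0)
        finite_h0 = sorted(iv.death for iv in diag.in_dim(0) if np.isfinite(iv.death))
        assert finite_h0 == [1.0, 2.0]

    def test_unit_square_single_h1(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        diag = ss.rips_persistence(squareform(pdist(pts)), max_radius=2.0)
        h1 = diag.in_dim(1)
        assert len(h1) == 1
        assert h1[0].birth == pytest.approx(1.0, abs=1e-12)
        assert h1[0].death == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_duplicate_point_changes_no_h1_interval(self, rng):
        pts = ss.gen_circle_cloud(30, 1.0, 0.05, seed=4)
        dup = np.vstack([pts, pts[7]])
        d1 = ss.rips_persistence(squareform(pdist(pts)), max_radius=3.0)
        d2 = ss.rips_persistence(squareform(pdist(dup)), max_radius=3.0)
        h1a = [(iv.birth, iv.death) for iv in d1.in_dim(1)]
        h1b = [(iv.birth, iv.death) for iv in d2.in_dim(1)]
        assert h1a == h1b

    def test_h0_conservation(self, rng):
        """Finite H0 intervals + components at max_radius = n points."""
        pts = rng.standard_normal((20, 3))
        dm = squareform(pdist(pts))
        r = float(np.median(dm))
        diag = ss.rips_persistence(dm, max_radius=r)
        finite = sum(1 for iv in diag.in_dim(0) if np.isfinite(iv.death))
        essential = sum(1 for iv in diag.in_dim(0) if not np.isfinite(iv.death))
        assert finite + essential == 20

    def test_small_radius_warns_isolated(self):
        dm = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="isolated"):
            diag = ss.rips_persistence(dm, max_radius=0.5)
        assert all(not np.isfinite(iv.death) for iv in diag.in_dim(0))

    def test_point_guard(self, rng):
        dm = squareform(pdist(rng.standard_normal((30, 2))))
        with pytest.raises(ValueError, match="maxmin_landmarks"):
            ss.rips_persistence(dm, max_points=20)

    def test_matches_brute_force_on_random_clouds(self, rng):
        """Spot-check against the full-boundary-matrix oracle (more draws
        in the acceptance suite)."""
        for _ in range(10):
            n = int(rng.integers(4, 15))
            pts = rng.uniform(size=(n, int(rng.integers(2, 4))))
            dm = squareform(pdist(pts))
            mine = diagram_to_tuples(ss.rips_persistence(dm, max_radius=float(dm.max())))
            assert mine == brute_force_persistence(dm)


class TestBettiCurve:
    def test_counts_at_example_radii(self):
        diag = ss.PersistenceDiagram(
            intervals=[
                PersistenceInterval(1, 0.1, 0.9),
                PersistenceInterval(1, 0.2, 0.5),
            ],
            max_radius=1.0,
        )
        curve = ss.betti_curve(diag, 1, np.array([0.3, 0.7, 0.95]))
        assert curve.counts.tolist() == [2, 1, 0]

    def test_zero_beyond_largest_death(self, rng):
        pts = rng.standard_normal((15, 2))
        dm = squareform(pdist(pts))
        diag = ss.rips_persistence(dm, max_radius=float(dm.max()))
        top = max(iv.death for iv in diag.in_dim(1)) if diag.in_dim(1) else 1.0
        curve = ss.betti_curve(diag, 1, np.array([top + 1.0]))
        assert curve.counts[0] == 0

    def test_consistent_with_direct_interval_counting(self, rng):
        pts = ss.gen_circle_cloud(25, 1.0, 0.2, seed=11)
        dm = squareform(pdist(pts))
        diag = ss.rips_persistence(dm, max_radius=float(dm.max()))
        grid = default_grid(diag, 50)
        curve = ss.betti_curve(diag, 1, grid)
        direct = [
            sum(1 for iv in diag.in_dim(1) if iv.birth <= g < iv.death) for g in grid
        ]
        assert curve.counts.tolist() == direct

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ss.betti_curve(ss.PersistenceDiagram(), 1, np.array([]))


class TestTdaSummaries:
    def test_worked_example(self):
        diag = ss.PersistenceDiagram(
            intervals=[
                PersistenceInterval(1, 0.2, 0.5),
                PersistenceInterval(1, 0.1, 0.9),
            ],
            max_radius=1.0,
        )
        out = ss.tda_summaries(diag, np.linspace(0, 1, 101))
        assert out["max_persistence"] == pytest.approx(0.8)
        assert out["n_cycles"] == 2
        assert out["max_cycles"] == 2

    def test_empty_h1_gives_zeros(self):
        diag = ss.PersistenceDiagram(intervals=[PersistenceInterval(0, 0.0, np.inf)], max_radius=1.0)
        out = ss.tda_summaries(diag)
        assert (out["max_persistence"], out["n_cycles"], out["max_cycles"]) == (0.0, 0.0, 0.0)
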