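"""Feature extraction: streams, smoothing, binning, invariances."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import poseseg as ps
from poseseg.errors import ParameterError
from poseseg.features import RawFeatures, bin_features, smooth_features

from conftest import random_walk_pose


def brute_force_streams(p, signed):
    """Naive per-pair double-loop reference for the L, Θ, D streams."""
    t, n = p.coords.shape[:2]
    pairs = list(combinations(range(n), 2))
    dist = np.zeros((t - 1, len(pairs)))
    ang = np.zeros((t - 1, len(pairs)))
    disp = np.zeros((t - 1, n))
    for ti in range(t - 1):
        for m, (i, j) in enumerate(pairs):
            v0 = p.coords[ti, j] - p.coords[ti, i]
            v1 = p.coords[ti + 1, j] - p.coords[ti + 1, i]
            dist[ti, m] = np.hypot(*v1)
            a = np.degrees(
                np.arctan2(v0[0] * v1[1] - v0[1] * v1[0], v0 @ v1)
            )
            ang[ti, m] = a if signed else abs(a)
        for k in range(n):
            disp[ti, k] = np.linalg.norm(p.coords[ti + 1, k] - p.coords[ti, k])
    return dist, ang, disp


class TestRawFeatures:
    def test_six_parts_give_36_features(self):
        p = random_walk_pose(n_parts=6, t=30)
        fm = ps.pose_to_features(p)
        assert fm.values.shape[1] == 36
        prefixes = [nm.split(":")[0] for nm in fm.feature_names]
        assert prefixes.count("dist") == 15
        assert prefixes.count("ang") == 15
        assert prefixes.count("disp") == 6

    def test_static_pose(self, static_pose):
        raw = ps.raw_features(static_pose)
        np.testing.assert_allclose(raw.displacements, 0.0, atol=1e-12)
        np.testing.assert_allclose(raw.angles, 0.0, atol=1e-12)
        assert np.ptp(raw.distances, axis=0).max() < 1e-12

    @pytest.mark.parametrize("signed", [True, False])
    def test_matches_brute_force_oracle(self, signed):
        p = random_walk_pose(n_parts=3, t=50, seed=7)
        raw = ps.raw_features(p, signed_angles=signed)
        dist, ang, disp = brute_force_streams(p, signed)
        np.testing.assert_allclose(raw.distances, dist, atol=1e-9)
        np.testing.assert_allclose(raw.angles, ang, atol=1e-9)
        np.testing.assert_allclose(raw.displacements, disp, atol=1e-9)

    def test_coincident_points_give_zero_angle(self):
        coords = np.zeros((5, 2, 2))
        coords[:, 1] = 0.0  # both parts at the origin: zero-length pair vector
        p = ps.PoseSeries(
            ["a", "b"], coords, np.full((5, 2), 0.9), fps=60.0
        )
        raw = ps.raw_features(p)
        assert np.isfinite(raw.angles).all()
        np.testing.assert_allclose(raw.angles, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 6])
    def test_column_count_is_n_squared(self, n):
        p = random_walk_pose(n_parts=n, t=25, seed=n)
        fm = ps.pose_to_features(p)
        assert fm.values.shape[1] == n * n


class TestInvariances:
    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
    )
    def test_translation_invariance(self, dx, dy):
        p = random_walk_pose(n_parts=3, t=30, seed=2)
        q = ps.PoseSeries(
            p.bodyparts, p.coords + np.array([dx, dy]), p.likelihood, p.fps
        )
        a, b = ps.pose_to_features(p), ps.pose_to_features(q)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    @given(angle=st.floats(-np.pi, np.pi))
    def test_rotation_invariance(self, angle):
        p = random_walk_pose(n_parts=3, t=30, seed=4)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        q = ps.PoseSeries(
            p.bodyparts, p.coords @ rot.T, p.likelihood, p.fps
        )
        a = ps.pose_to_features(p)  # unsigned |Θ| is rotation invariant
        b = ps.pose_to_features(q)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)


class TestSmoothing:
    def test_60fps_half_width_and_impulse(self):
        t = 101
        stream = np.zeros((t, 1))
        stream[50, 0] = 7.0
        raw = RawFeatures(
            stream, np.zeros((t, 1)), np.zeros((t, 2)),
            ["a", "b"], fps=60.0,
        )
        sm = smooth_features(raw)
        # half-width round(0.03 * 60) = 2 -> 5-frame window
        assert sm.distances[50, 0] == pytest.approx(7.0 / 5)
        assert sm.distances[47, 0] == 0.0
        assert sm.distances[48, 0] == pytest.approx(7.0 / 5)

    def test_constant_stream_unchanged(self):
        raw = RawFeatures(
            np.full((40, 1), 3.0), np.zeros((40, 1)), np.zeros((40, 2)),
            ["a", "b"], fps=60.0,
        )
        sm = smooth_features(raw)
        np.testing.assert_allclose(sm.distances, 3.0, atol=1e-12)

    def test_edges_truncated_not_padded(self):
        stream = np.ones((10, 1))
        raw = RawFeatures(
            stream, np.zeros((10, 1)), np.zeros((10, 2)), ["a", "b"], fps=60.0
        )
        sm = smooth_features(raw)
        np.testing.assert_allclose(sm.distances, 1.0, atol=1e-12)


class TestBinning:
    def test_bin_count_60fps(self):
        p = random_walk_pose(n_parts=2, t=600, fps=60.0)
        fm = ps.pose_to_features(p)
        # 599 transitions in windows of 6 -> 99 complete bins
        assert fm.n_bins == 99
        assert fm.bin_rate == pytest.approx(10.0)

    def test_constant_distance_is_averaged(self, static_pose):
        fm = ps.pose_to_features(static_pose)
        dist0 = np.linalg.norm(
            static_pose.coords[0, 1] - static_pose.coords[0, 0]
        )
        np.testing.assert_allclose(fm.values[:, 0], dist0, atol=1e-9)

    def test_unit_displacement_sums_to_window(self):
        t, fps = 121, 60.0
        coords = np.zeros((t, 2, 2))
        coords[:, 0, 0] = np.arange(t)  # 1 px/frame along x
        coords[:, 1, 1] = 50.0
        p = ps.PoseSeries(["a", "b"], coords, np.full((t, 2), 0.9), fps=fps)
        fm = ps.pose_to_features(p)
        disp_a = fm.values[:, fm.feature_names.index("disp:a")]
        np.testing.assert_allclose(disp_a, 6.0, atol=1e-9)

    def test_low_fps_rejected(self):
        p = random_walk_pose(n_parts=2, t=50, fps=5.0)
        with pytest.raises(ParameterError, match="unsupported"):
            ps.pose_to_features(p)

    def test_offset_out_of_range_rejected(self):
        p = random_walk_pose(n_parts=2, t=50, fps=30.0)
        with pytest.raises(ParameterError, match="offset"):
            ps.pose_to_features(p, offset=3)

    def test_offset_shifts_the_grid(self):
        p = random_walk_pose(n_parts=2, t=100, fps=30.0)
        raw = smooth_features(ps.raw_features(p))
        f0 = bin_features(raw, offset=0)
        f1 = bin_features(raw, offset=1)
        assert abs(f0.n_bins - f1.n_bins) <= 1
        assert not np.allclose(
            f0.values[: f1.n_bins - 1], f1.values[: f1.n_bins - 1]
        )


def test_feature_matrix_round_trips(tmp_path):
    p = random_walk_pose(n_parts=3, t=60)
    fm = ps.pose_to_features(p)
    fm.to_csv(tmp_path / "f.csv")
    back = ps.FeatureMatrix.from_csv(tmp_path / "f.csv", source_fps=60.0)
    np.testing.assert_allclose(back.values, fm.values, atol=1e-9)
    assert back.feature_names == fm.feature_names
    fm.to_hdf5(tmp_path / "f.h5")
    back5 = ps.FeatureMatrix.from_hdf5(tmp_path / "f.h5")
    np.testing.assert_allclose(back5.values, fm.values, atol=1e-12)
    assert back5.feature_names == fm.feature_names
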