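"""Motion-energy comparisons and spike-alignment analyses."""

import numpy as np
import pytest

import poseseg as ps
from poseseg.errors import ParameterError, PosesegError
from poseseg.frameshift import Bout
from poseseg.validation import PETH, _mse


def centered_pose(t, fps=30.0, h=64, w=64):
    coords = np.tile(np.array([[w / 2, h / 2], [w / 2, h / 2]]), (t, 1, 1))
    return ps.PoseSeries(
        ["a", "b"], coords, np.full((t, 2), 0.99), fps=fps
    )


class TestMotionEnergyImage:
    def test_static_scene_is_zero(self):
        frames = np.ones((20, 32, 32), dtype=np.float32)
        pose = centered_pose(20, h=32, w=32)
        me = ps.motion_energy_image(frames, Bout(0, 0, 20, 30.0), pose)
        np.testing.assert_allclose(me.pixels, 0.0, atol=1e-9)

    def test_moving_pixel_closed_form(self):
        # one bright pixel stepping 1 px/frame: each consecutive difference
        # holds |−1| at the old and |+1| at the new position, so the ME
        # image total is exactly 2 and each interior visited pixel averages
        # 2/n_diffs (entered once, left once)
        n = 11
        frames = np.zeros((n, 33, 33), dtype=np.float32)
        for t in range(n):
            frames[t, 16, 5 + t] = 1.0
        pose = centered_pose(n, h=33, w=33)
        me = ps.motion_energy_image(frames, Bout(0, 0, n, 30.0), pose)
        assert me.n_diff_frames == n - 1
        assert me.pixels.sum() == pytest.approx(2.0)
        np.testing.assert_allclose(
            me.pixels[16, 6 : 5 + n - 1], 2.0 / (n - 1), atol=1e-9
        )

    def test_registration_centers_start_pose(self):
        frames = np.zeros((5, 40, 40), dtype=np.float32)
        frames[:, 10, 10] = 1.0
        frames[0, 10, 10] = 0.0  # one change so ME is nonzero at (10,10)
        coords = np.tile(np.array([[10.0, 10.0], [10.0, 10.0]]), (5, 1, 1))
        pose = ps.PoseSeries(
            ["a", "b"], coords, np.full((5, 2), 0.99), fps=30.0
        )
        me = ps.motion_energy_image(frames, Bout(0, 0, 5, 30.0), pose)
        # centroid (10, 10) is shifted to the image center (20, 20)
        assert me.pixels[20, 20] > 0
        assert me.pixels[10, 10] == 0

    def test_identical_trajectories_identical_images(self, default_session):
        pose = default_session.pose
        small = ps.PoseSeries(
            pose.bodyparts,
            pose.coords[:200] / 4.0,
            pose.likelihood[:200],
            fps=pose.fps,
        )
        frames = ps.render_blob_video(small, shape=(96, 96), sigma=2.0)
        bout = Bout(0, 10, 25, small.fps)
        a = ps.motion_energy_image(frames, bout, small)
        b = ps.motion_energy_image(frames, bout, small)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_cap_limits_frames(self):
        frames = np.zeros((100, 16, 16), dtype=np.float32)
        pose = centered_pose(100, fps=30.0, h=16, w=16)
        me = ps.motion_energy_image(
            frames, Bout(0, 0, 100, 30.0), pose, cap_ms=600.0
        )
        assert me.n_diff_frames == round(0.6 * 30) - 1

    def test_bout_outside_video_rejected(self):
        frames = np.zeros((10, 16, 16), dtype=np.float32)
        pose = centered_pose(10, h=16, w=16)
        with pytest.raises(PosesegError, match="outside"):
            ps.motion_energy_image(frames, Bout(0, 50, 60, 30.0), pose)


def render_motif_images(motif_idx, n_bouts, seed, fps=30.0):
    """ME images of repeated bouts of one default motif on a small raster."""
    specs = [m for m in ps.default_motifs() if np.all(m.drift == 0)]
    s = ps.simulate_pose(
        specs=[specs[motif_idx], specs[(motif_idx + 1) % len(specs)]],
        duration=30.0,
        fps=fps,
        jitter_sd=0.2,
        dropout_rate=0.0,
        mean_dwell=1e6,  # a single motif spans the session
        initial_state=0,
        arena=(96.0, 96.0),
        scale=0.6,
        seed=seed,
    )
    frames = ps.render_blob_video(s.pose, shape=(96, 96), sigma=2.0)
    w = int(round(fps * 0.45))
    bouts = [
        Bout(int(s.true_labels[0]), i * w, (i + 1) * w, fps)
        for i in range(n_bouts)
    ]
    return [
        ps.motion_energy_image(frames, b, s.pose) for b in bouts
    ], int(s.true_labels[0])


class TestMEMseMatrix:
    def test_identical_images_give_null_comparison(self):
        img = np.ones((8, 8))
        groups = {
            0: [ps.MEImage(img, Bout(0, 0, 10, 30.0), 9) for _ in range(3)],
            1: [ps.MEImage(img, Bout(1, 0, 10, 30.0), 9) for _ in range(3)],
        }
        cmp_ = ps.me_mse_matrix(groups, seed=0)
        np.testing.assert_allclose(cmp_.mse, 0.0)
        assert cmp_.ks_pvalue == pytest.approx(1.0)

    def test_mse_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        assert _mse(a, b) == pytest.approx(
            float(np.sum((a - b) ** 2)) / a.size, abs=1e-12
        )

    def test_matrix_symmetric_zero_diagonal_rows_normalized(self):
        rng = np.random.default_rng(1)
        groups = {
            g: [
                ps.MEImage(rng.random((10, 10)), Bout(g, 0, 10, 30.0), 5)
                for _ in range(4)
            ]
            for g in range(3)
        }
        cmp_ = ps.me_mse_matrix(groups, seed=1)
        np.testing.assert_allclose(cmp_.mse, cmp_.mse.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cmp_.mse), 0.0)
        # every row's in-group mean (off-diagonal) is exactly 1
        n = cmp_.normalized.shape[0]
        for i in range(n):
            same = (cmp_.group_of_row == cmp_.group_of_row[i]) & (
                np.arange(n) != i
            )
            assert cmp_.normalized[i, same].mean() == pytest.approx(1.0)

    def test_distinct_motifs_separate_in_vs_out(self):
        # two motifs with distinct blob dynamics, several bouts each
        imgs_a, lab_a = render_motif_images(0, 12, seed=3)
        imgs_b, lab_b = render_motif_images(1, 12, seed=4)
        cmp_ = ps.me_mse_matrix({0: imgs_a, 1: imgs_b}, seed=5)
        assert cmp_.out_group.mean() > cmp_.in_group.mean()
        assert cmp_.ks_pvalue < 0.01
        # structureless control: shuffled groups show no separation
        assert cmp_.shuffled_ks_pvalue > 0.1

    def test_small_group_dropped_with_notice(self):
        rng = np.random.default_rng(2)
        groups = {
            0: [ps.MEImage(rng.random((6, 6)), Bout(0, 0, 9, 30.0), 5)],
            1: [
                ps.MEImage(rng.random((6, 6)), Bout(1, 0, 9, 30.0), 5)
                for _ in range(3)
            ],
        }
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ParameterError):
                ps.me_mse_matrix(groups, seed=0)

    def test_eligible_bouts_duration_window(self):
        bouts = [Bout(0, 0, n, 60.0) for n in (10, 20, 30, 40)]
        kept = ps.eligible_bouts(bouts, 300.0, 600.0)
        assert [b.n_frames for b in kept] == [20, 30]


class TestAlignSpikes:
    def test_homogeneous_neuron_has_flat_z(self):
        sim = ps.simulate_poisson_neuron(
            baseline=8.0, elevated=8.0, n_trials=500, seed=11
        )
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        assert (np.abs(peth.z[0]) < 3).mean() >= 0.99

    def test_deterministic_spike_peaks_at_latency(self):
        onsets = 2.0 + np.arange(100) * 3.0
        spikes = onsets + 0.050
        peth = ps.align_spikes([spikes], onsets)
        peak = peth.centers[np.argmax(peth.z_smooth[0])]
        assert peak == pytest.approx(0.055, abs=0.031)
        raw_peak = peth.centers[np.argmax(peth.rate[0])]
        assert raw_peak == pytest.approx(0.055, abs=0.006)

    def test_z_rows_standardized_before_smoothing(self):
        sim = ps.simulate_poisson_neuron(n_trials=100, seed=12)
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        np.testing.assert_allclose(peth.z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(peth.z.std(axis=1), 1.0, atol=1e-9)

    def test_window_and_bin_grid(self):
        sim = ps.simulate_poisson_neuron(n_trials=10, seed=13)
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        assert peth.rate.shape[1] == 300
        assert peth.edges[0] == pytest.approx(-1.0)
        assert peth.edges[-1] == pytest.approx(2.0)

    def test_empty_train_yields_zero_row(self):
        with pytest.warns(UserWarning, match="no spikes"):
            peth = ps.align_spikes([np.array([])], [1.0, 2.0])
        np.testing.assert_array_equal(peth.rate[0], 0.0)

    def test_plateau_recovers_elevated_rate(self):
        sim = ps.simulate_poisson_neuron(
            baseline=5.0, elevated=15.0, n_trials=500, seed=14
        )
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        c = peth.centers
        window = (c >= -0.130) & (c < -0.030)
        assert peth.rate[0, window].mean() == pytest.approx(15.0, rel=0.10)

    def test_rank_order_sorts_by_preonset_activity(self):
        onsets = 2.0 + np.arange(200) * 3.0
        rng = np.random.default_rng(15)
        quiet = rng.uniform(0, 610, 3000)  # ~5 Hz background
        active = np.concatenate(
            [quiet, (onsets[:, None] + rng.uniform(-0.2, 0.0, (200, 4))).ravel()]
        )
        peth = ps.align_spikes([quiet, active], onsets)
        order = ps.rank_order(peth)
        assert order[0] == 1


class TestSignalMagnitudeDifference:
    def test_equal_peths_give_zero(self):
        sim = ps.simulate_poisson_neuron(n_trials=50, seed=16)
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        diff = ps.signal_magnitude_difference(peth, peth)
        np.testing.assert_allclose(diff.summed, 0.0, atol=1e-12)
        assert not diff.significant.any()

    def test_hand_computed_example(self):
        edges = np.array([0.0, 0.01, 0.02, 0.03])
        mk = lambda z: PETH(
            rate=np.abs(z), z=z, z_smooth=z, edges=edges, n_bouts=1
        )
        high = mk(np.array([[1.0, -2.0, 0.5], [0.0, 1.0, -1.0]]))
        low = mk(np.array([[0.5, -1.0, 1.5], [0.0, 2.0, -1.0]]))
        diff = ps.signal_magnitude_difference(high, low)
        np.testing.assert_allclose(
            diff.per_neuron, [[0.5, 1.0, -1.0], [0.0, -1.0, 0.0]]
        )
        np.testing.assert_allclose(diff.summed, [0.5, 0.0, -1.0])
        np.testing.assert_allclose(diff.mean, [0.25, 0.0, -0.5])

    def test_grid_mismatch_rejected(self):
        sim = ps.simulate_poisson_neuron(n_trials=20, seed=17)
        peth = ps.align_spikes([sim.spike_times], sim.true_onsets)
        other = ps.align_spikes(
            [sim.spike_times], sim.true_onsets, window=(-0.5, 1.0)
        )
        with pytest.raises(ParameterError, match="bin grid"):
            ps.signal_magnitude_difference(peth, other)

    def test_coarse_jitter_degrades_onset_signal(self):
        # several simulated neurons, aligned with 60 fps vs 10 fps onset
        # jitter: the high-resolution alignment carries the stronger
        # modulation signal around onset, and loses it later (biphasic)
        highs, lows = [], []
        onsets = None
        for i in range(6):
            sim60 = ps.simulate_poisson_neuron(
                n_trials=400, jitter_fps=60.0, seed=100 + i
            )
            sim10 = ps.simulate_poisson_neuron(
                n_trials=400, jitter_fps=10.0, seed=100 + i
            )
            highs.append(
                ps.align_spikes([sim60.spike_times], sim60.reported_onsets)
            )
            lows.append(
                ps.align_spikes([sim10.spike_times], sim10.reported_onsets)
            )
        high = PETH(
            rate=np.vstack([p.rate for p in highs]),
            z=np.vstack([p.z for p in highs]),
            z_smooth=np.vstack([p.z_smooth for p in highs]),
            edges=highs[0].edges,
            n_bouts=400,
        )
        low = PETH(
            rate=np.vstack([p.rate for p in lows]),
            z=np.vstack([p.z for p in lows]),
            z_smooth=np.vstack([p.z_smooth for p in lows]),
            edges=lows[0].edges,
            n_bouts=400,
        )
        diff = ps.signal_magnitude_difference(high, low)
        c = diff.centers
        inside = (c >= -0.13) & (c < -0.03)
        smear = (c >= -0.01) & (c < 0.07)
        assert diff.mean[inside].mean() > 0  # sharper signal in the window
        assert diff.mean[smear].mean() < 0  # low-res smears activity later
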