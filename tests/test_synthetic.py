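"""Synthetic prototype clips, rendering, and simulated observers."""

import numpy as np
import pandas as pd
import pytest

import xfaces as xf
from xfaces.synthetic import softmax_probabilities


class TestPrototypeGeneration:
    def test_default_marker_and_frame_counts(self, prototype_set):
        # 43 facial markers, 5 s at 30 Hz → 150 frames
        for traj in prototype_set.prototypes.values():
            assert traj.n_markers == 43
            assert traj.n_frames == 150
        assert prototype_set.neutral.n_markers == 43

    def test_first_and_last_frames_equal_neutral(self, prototype_set):
        pose = prototype_set.neutral_pose
        for name, traj in prototype_set.prototypes.items():
            amp = np.abs(traj.positions - pose).max()
            assert np.allclose(traj.positions[0], pose, atol=1e-9 * max(amp, 1)), name
            assert np.allclose(traj.positions[-1], pose, atol=1e-9 * max(amp, 1)), name

    def test_neutral_is_static(self, prototype_set):
        assert np.all(np.diff(prototype_set.neutral.positions, axis=0) == 0)

    def test_zero_amplitude_gives_neutral(self):
        ps = xf.gen_prototype_trajectories(xf.PrototypeSpec(amplitude=0.0), seed=0)
        for traj in ps.prototypes.values():
            assert np.array_equal(traj.positions, ps.neutral.positions)

    def test_prototypes_differ_in_pattern_and_timing(self, prototype_set):
        pose = prototype_set.neutral_pose
        peak_frames = {}
        for name, traj in prototype_set.prototypes.items():
            disp = np.linalg.norm(traj.positions - pose, axis=2).sum(axis=1)
            peak_frames[name] = int(np.argmax(disp))
        assert len(set(peak_frames.values())) >= 3  # distinct peak timings
        # monkey prototypes move the ears, human ones do not
        ear_idx = [i for i, m in enumerate(prototype_set.neutral.marker_ids) if m.startswith("ear")]
        for name, traj in prototype_set.prototypes.items():
            ear_disp = np.abs(traj.positions[:, ear_idx] - pose[ear_idx]).max()
            if name.startswith("monkey"):
                assert ear_disp > 1.0
            else:
                assert ear_disp == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            xf.PrototypeSpec(duration_s=-1.0)
        with pytest.raises(ValueError):
            xf.PrototypeSpec(frame_rate=0.0)
        with pytest.raises(ValueError):
            xf.PrototypeSpec(marker_count=2)


class TestRenderFrames:
    def test_static_input_gives_identical_frames(self, prototype_set):
        frames = xf.render_frames(prototype_set.neutral.with_positions(
            prototype_set.neutral.positions[:5]), image_size=48)
        assert frames.shape == (5, 48, 48)
        assert np.all(frames == frames[0])
        assert frames.min() >= 0.0 and frames.max() <= 1.0

    def test_translated_marker_shifts_centroid(self):
        # one marker moving 5 px/frame between two frames (centroid oracle)
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 5.0
        # add static far-away markers so the affine scale is fixed by a
        # bounding box much larger than the motion
        anchors = np.array([[-50.0, -50.0, 0.0], [50.0, 50.0, 0.0]])
        pos = np.concatenate([pos, np.broadcast_to(anchors, (2, 2, 3))], axis=1)
        traj = xf.MarkerTrajectory(pos, frame_rate=30.0)
        size, sigma = 128, 2.0
        frames = xf.render_frames(traj, image_size=size, blob_sigma=sigma)
        scale = (size - 1 - 2 * 3 * sigma) / 100.0  # bbox span is 100 units

        def centroid(img):
            g = np.arange(img.shape[0], dtype=float)
            total = img.sum()
            return (img * g[None, :]).sum() / total, (img * g[:, None]).sum() / total

        # isolate the moving blob (left half of image is free of anchors)
        sub0 = frames[0][40:88, 40:88]
        sub1 = frames[1][40:88, 40:88]
        cx0, _ = centroid(sub0)
        cx1, _ = centroid(sub1)
        assert abs((cx1 - cx0) - 5.0 * scale) < 0.2

    def test_translation_equivariance_via_cross_correlation(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(-20, 20, size=(8, 3))
        shift = np.array([4.0, 0.0, 0.0])
        pos = np.stack([base, base + shift])
        traj = xf.MarkerTrajectory(pos, frame_rate=30.0)
        size, sigma = 96, 2.0
        frames = xf.render_frames(traj, image_size=size, blob_sigma=sigma)
        xy = pos[:, :, :2]
        span = max(np.ptp(xy[..., 0]), np.ptp(xy[..., 1]))
        scale = (size - 1 - 2 * 3 * sigma) / span
        f0 = np.fft.fft2(frames[0])
        f1 = np.fft.fft2(frames[1])
        corr = np.fft.ifft2(np.conj(f0) * f1).real
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        # parabolic sub-pixel refinement along the column axis
        c = corr[peak[0], :]
        i = peak[1]
        num = c[(i - 1) % size] - c[(i + 1) % size]
        den = c[(i - 1) % size] - 2 * c[i] + c[(i + 1) % size]
        dx = i + 0.5 * num / den if den != 0 else float(i)
        if dx > size / 2:
            dx -= size
        assert abs(dx - shift[0] * scale) <= 0.5

    def test_too_small_image_rejected(self, prototype_set):
        with pytest.raises(ValueError):
            xf.render_frames(prototype_set.neutral, image_size=8, blob_sigma=4.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            xf.MarkerTrajectory(np.zeros((0, 3, 3)), 30.0)


class TestObserverSimulation:
    def test_row_count_and_schema(self, lattice_points):
        obs = xf.ObserverConfig(seed=1, n_participants=3, n_reps=2)
        resp = xf.gen_observer_responses(lattice_points, obs)
        assert len(resp) == 3 * 2 * 25 * 4  # participants × reps × cells × conditions
        assert set(resp["response_class"].unique()) <= {1, 2, 3, 4}
        assert set(resp["avatar"].unique()) == {"monkey", "human"}

    def test_determinism_bit_for_bit(self, lattice_points):
        obs = xf.ObserverConfig(seed=42, n_participants=2, n_reps=2)
        a = xf.gen_observer_responses(lattice_points, obs)
        b = xf.gen_observer_responses(lattice_points, obs)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_beta_gives_uniform_frequencies(self, lattice_points):
        obs = xf.ObserverConfig(
            beta_true=np.zeros((4, 3)), seed=2, n_participants=10, n_reps=10,
            conditions=(("monkey", 0),),
        )
        resp = xf.gen_observer_responses(lattice_points, obs)
        freq = resp["response_class"].value_counts(normalize=True)
        # 2500 trials; binomial SE of a 0.25 proportion ≈ 0.0087
        assert np.all(np.abs(freq - 0.25) < 4 * 0.0087)

    def test_frequencies_match_analytic_softmax(self, lattice_points):
        # strong e-slope for class 1; empirical cell frequencies within 3 SE
        beta = np.zeros((4, 3))
        beta[0] = [-2.0, 4.0, 0.0]
        obs = xf.ObserverConfig(
            beta_true=beta, seed=1, n_participants=20, n_reps=10,
            conditions=(("monkey", 0),),
        )
        resp = xf.gen_observer_responses(lattice_points, obs)
        n = 200
        for e, s in [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)]:
            p = softmax_probabilities(beta, e, s)
            cell = resp[(resp["e"] == e) & (resp["s"] == s)]
            for j in range(4):
                obs_freq = np.mean(cell["response_class"] == j + 1)
                se = np.sqrt(p[j] * (1 - p[j]) / n)
                assert abs(obs_freq - p[j]) <= 3 * max(se, 1e-3)

    def test_invalid_coordinates_rejected(self):
        obs = xf.ObserverConfig(seed=0)
        with pytest.raises(ValueError):
            xf.gen_observer_responses([(0.5, 1.5)], obs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            xf.ObserverConfig(n_participants=0)
        with pytest.raises(ValueError):
            xf.ObserverConfig(beta_true=np.zeros((3, 3)))
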