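"""Expressiveness measures (MF, DF, OF) and equilibration."""

import numpy as np
import pytest

import xfaces as xf
from xfaces.expressiveness import _logistic
from xfaces.trajectory import AlignmentError

from conftest import make_linear_trajectory


def static_trajectory(n_frames=5, n_markers=4):
    return make_linear_trajectory(n_frames, n_markers, velocity=(0, 0, 0))


class TestMotionFlow:
    def test_zero_for_static(self):
        assert xf.motion_flow_MF(static_trajectory()).value == 0.0

    def test_single_marker_path_length(self):
        # one marker moves along a straight 2D path of total length 12
        pos = np.zeros((7, 2, 3))
        pos[:, 0, 0] = np.linspace(0, 12, 7)  # 2 units/frame × 6 steps
        pos[:, 1, :] = 5.0  # static marker
        traj = xf.MarkerTrajectory(pos, frame_rate=30.0)
        assert xf.motion_flow_MF(traj).value == pytest.approx(12.0, abs=1e-12)

    def test_z_motion_excluded(self):
        pos = np.zeros((5, 1, 3))
        pos[:, 0, 2] = np.arange(5.0)  # pure depth motion
        traj = xf.MarkerTrajectory(pos, frame_rate=30.0)
        assert xf.motion_flow_MF(traj).value == 0.0
        # the 30° rotated view projects part of z onto the image plane
        assert xf.motion_flow_MF(traj, view_deg=30.0).value == pytest.approx(
            4 * np.sin(np.deg2rad(30.0)), rel=1e-12
        )

    def test_linearity_in_morph_level(self, prototype_set):
        traj = prototype_set.prototypes["monkey-threat"]
        neutral = prototype_set.neutral
        full = xf.motion_flow_MF(traj).value
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            morphed = xf.neutral_morph(traj, neutral, lam)
            assert xf.motion_flow_MF(morphed).value == pytest.approx(
                lam * full, rel=1e-9, abs=1e-9
            )

    def test_region_mask_and_errors(self, prototype_set):
        traj = prototype_set.prototypes["monkey-threat"]
        mouth = [m for m in traj.marker_ids if m.startswith("mouth")]
        partial = xf.motion_flow_MF(traj, region=mouth).value
        assert 0 < partial < xf.motion_flow_MF(traj).value
        with pytest.raises(ValueError):
            xf.motion_flow_MF(traj, region=[])
        with pytest.raises(AlignmentError):
            xf.motion_flow_MF(traj, region=["nosuchmarker"])

    def test_translation_invariance(self, prototype_set):
        traj = prototype_set.prototypes["human-angry"]
        shifted = traj.with_positions(traj.positions + np.array([3.0, -2.0, 7.0]))
        assert xf.motion_flow_MF(shifted).value == pytest.approx(
            xf.motion_flow_MF(traj).value, rel=1e-12
        )


class TestDeformation:
    def test_zero_when_equal_to_neutral(self):
        t = static_trajectory()
        assert xf.deformation_DF(t, t.positions[0]).value == 0.0

    def test_3_4_5_norm_excludes_z(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 0] = [3.0, 4.0, 99.0]
        traj = xf.MarkerTrajectory(pos, frame_rate=30.0)
        neutral = np.zeros((2, 3))
        assert xf.deformation_DF(traj, neutral).value == pytest.approx(5.0, abs=1e-12)

    def test_maximum_attained_at_activation_peak(self, prototype_set):
        traj = prototype_set.prototypes["human-fear"]
        pose = prototype_set.neutral_pose
        # frame-wise scan oracle
        diffs = (traj.positions - pose)[:, :, :2].reshape(traj.n_frames, -1)
        per_frame = np.linalg.norm(diffs, axis=1)
        assert xf.deformation_DF(traj, pose).value == pytest.approx(per_frame.max())
        peak = int(np.argmax(per_frame))
        assert 0 < peak < traj.n_frames - 1  # mid-sequence

    def test_marker_mismatch_error(self, prototype_set):
        with pytest.raises(AlignmentError):
            xf.deformation_DF(prototype_set.prototypes["human-fear"], np.zeros((3, 3)))


class TestOpticFlow:
    def test_zero_for_identical_frames(self):
        frames = np.zeros((3, 32, 32))
        frames[:, 10:20, 10:20] = 0.5
        assert xf.optic_flow_OF(frames).value == 0.0

    def test_translated_blob_recovered_within_20_percent(self):
        # smooth Gaussian blob translated 1 px/frame
        size = 64
        yy, xx = np.mgrid[0:size, 0:size]
        frames = np.stack(
            [np.exp(-((xx - 28 - d) ** 2 + (yy - 32) ** 2) / (2 * 4.0**2)) for d in range(3)]
        )
        u, v = xf.horn_schunck(frames[0], frames[1], alpha=0.1, iterations=1000)
        blob = frames[0] > 0.05
        mean_mag = np.hypot(u, v)[blob].mean()
        assert abs(mean_mag - 1.0) < 0.2
        assert abs(np.median(u[blob])) > abs(np.median(v[blob]))  # motion along x

    def test_flow_scales_linearly_for_subpixel_shifts(self):
        size = 48
        yy, xx = np.mgrid[0:size, 0:size]

        def blob(cx):
            return np.exp(-((xx - cx) ** 2 + (yy - 24) ** 2) / (2 * 3.0**2))

        shifts = [0.25, 0.5, 0.75, 1.0]
        mags = []
        for d in shifts:
            u, v = xf.horn_schunck(blob(20.0), blob(20.0 + d), iterations=200)
            mask = blob(20.0) > 0.05
            mags.append(np.hypot(u, v)[mask].mean())
        slope, intercept = np.polyfit(shifts, mags, 1)
        fitted = np.polyval([slope, intercept], shifts)
        assert np.corrcoef(shifts, mags)[0, 1] > 0.99
        assert np.max(np.abs(fitted - mags)) < 0.1 * max(mags)

    def test_invalid_settings_rejected(self):
        frames = np.zeros((2, 16, 16))
        with pytest.raises(ValueError):
            xf.optic_flow_OF(frames, alpha=0.0)
        with pytest.raises(ValueError):
            xf.optic_flow_OF(frames, iterations=0)
        with pytest.raises(ValueError):
            xf.optic_flow_OF(np.zeros((1, 16, 16)))


class TestEquilibrationCurve:
    def test_noiseless_recovery(self):
        lam = np.linspace(0, 1, 11)
        m = _logistic(lam, 0.0, 10.0, -6.0, 3.0)
        curve = xf.fit_equilibration_curve(list(zip(lam, m)))
        assert curve.fit_residual < 1e-6
        assert not curve.degenerate
        grid = np.linspace(0, 1, 101)
        assert np.allclose(curve(grid), _logistic(grid, 0.0, 10.0, -6.0, 3.0), atol=1e-6)

    def test_constant_samples_flagged_degenerate(self):
        lam = np.linspace(0, 1, 11)
        curve = xf.fit_equilibration_curve([(l, 5.0) for l in lam])
        assert curve.degenerate and curve.a1 == 0.0

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(3)
        lam = np.linspace(0, 1, 11)
        truth = _logistic(lam, 0.0, 10.0, -6.0, 3.0)
        noisy = truth + 0.02 * np.ptp(truth) * rng.standard_normal(len(lam))
        curve = xf.fit_equilibration_curve(list(zip(lam, noisy)))
        grid = np.linspace(0, 1, 101)
        target = _logistic(grid, 0.0, 10.0, -6.0, 3.0)
        assert np.max(np.abs(curve(grid) - target)) < 0.05 * np.ptp(target)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            xf.fit_equilibration_curve([(0.0, 1.0), (0.5, 2.0), (1.0, 3.0)])


class TestInvertCurve:
    @pytest.fixture()
    def curve(self):
        lam = np.linspace(0, 1, 11)
        m = _logistic(lam, 0.0, 10.0, -6.0, 3.0)
        return xf.fit_equilibration_curve(list(zip(lam, m)))

    def test_endpoint(self, curve):
        assert xf.invert_curve(curve, float(curve(1.0))) == pytest.approx(1.0, abs=1e-6)

    def test_round_trip_at_0_37(self, curve):
        target = float(curve(0.37))
        assert xf.invert_curve(curve, target) == pytest.approx(0.37, abs=1e-6)

    def test_target_out_of_range(self, curve):
        with pytest.raises(ValueError, match="attainable"):
            xf.invert_curve(curve, float(curve(1.0)) + 5.0)

    def test_degenerate_curve_rejected(self):
        lam = np.linspace(0, 1, 11)
        curve = xf.fit_equilibration_curve([(l, 2.0) for l in lam])
        with pytest.raises(ValueError):
            xf.invert_curve(curve, 2.0)


class TestEquilibratePrototypes:
    def test_identical_prototypes_all_lambda_one(self, prototype_set):
        traj = prototype_set.prototypes["monkey-threat"]
        same = xf.PrototypeSet(
            {k: traj for k in xf.PROTOTYPE_ORDER},
            prototype_set.neutral,
            prototype_set.spec,
        )
        res = xf.equilibrate_prototypes(same, "MF")
        assert all(lam == pytest.approx(1.0, abs=1e-6) for lam in res.lambda_per_prototype.values())

    def test_linear_mf_ratios_invert_exactly(self, prototype_set):
        # MF is linear in λ against a static neutral, so prototypes with MF
        # ratios (1, 2, 2, 4) should equilibrate at λ ≈ (1, 0.5, 0.5, 0.25)
        base = prototype_set.prototypes["monkey-threat"]
        neutral = prototype_set.neutral

        def scaled(f):
            disp = base.positions - neutral.positions
            return base.with_positions(neutral.positions + f * disp)

        protos = xf.PrototypeSet(
            {
                "monkey-fear": scaled(1.0),
                "monkey-threat": scaled(2.0),
                "human-fear": scaled(2.0),
                "human-angry": scaled(4.0),
            },
            neutral,
            prototype_set.spec,
        )
        res = xf.equilibrate_prototypes(protos, "MF")
        lam = res.lambda_per_prototype
        assert lam["monkey-fear"] == pytest.approx(1.0, abs=1e-3)
        assert lam["monkey-threat"] == pytest.approx(0.5, abs=0.01)
        assert lam["human-fear"] == pytest.approx(0.5, abs=0.01)
        assert lam["human-angry"] == pytest.approx(0.25, abs=0.01)
        assert res.within_tolerance()

    def test_equilibration_reduces_grid_sd(self, prototype_set, style_grid):
        res = xf.equilibrate_prototypes(prototype_set, "MF")
        eq_protos = {
            name: xf.neutral_morph(traj, prototype_set.neutral, res.lambda_per_prototype[name])
            for name, traj in prototype_set.prototypes.items()
        }
        eq_grid = xf.build_style_grid(eq_protos, 5)
        pose = prototype_set.neutral_pose
        sd_before = xf.grid_measure_sd(style_grid.trajectories, pose, "MF")
        sd_after = xf.grid_measure_sd(eq_grid.trajectories, pose, "MF")
        assert sd_after < sd_before
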