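"""Feature extraction: side selection, normalisation, angles, derivatives,
flip/noise operators and their invariances."""

import numpy as np
import pytest

from liftload import kinematics as kin
from liftload import pose_io
from liftload.kinematics import (
    ACC,
    ANG,
    FLIP_SIGN,
    POS,
    VEL,
    FeatureSequence,
    KinematicsError,
    SagittalJoints,
    add_gaussian_noise,
    assemble_features,
    compute_angles,
    compute_derivatives,
    extract_sagittal_joints,
    flip_features,
    normalize_positions,
    select_side,
)
from liftload.synthetic import SimConfig, make_profiles, simulate_lift_instance

from conftest import make_track


def _track_with_conf(left=0.9, right=0.9, T=4):
    kpts = np.zeros((T, pose_io.N_KEYPOINTS, 3))
    kpts[:, :, :2] = 100.0
    for name, c in (("left", left), ("right", right)):
        for j in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle"):
            kpts[:, pose_io.COCO_INDEX[f"{name}_{j}"], 2] = c
    kpts[:, pose_io.COCO_INDEX["nose"], 2] = 0.9
    return pose_io.track_from_arrays(kpts, None, fps=30, video_id="c")


class TestSelectSide:
    def test_higher_confidence_side_wins(self):
        assert select_side(_track_with_conf(left=0.4, right=0.9)) == "right"
        assert select_side(_track_with_conf(left=0.9, right=0.4)) == "left"

    def test_tie_breaks_right(self):
        assert select_side(_track_with_conf(left=0.7, right=0.7)) == "right"

    def test_both_sides_invisible_rejected(self):
        with pytest.raises(KinematicsError, match="both sides"):
            select_side(_track_with_conf(left=0.1, right=0.1))

    def test_simulated_occluded_side(self, sim_config, profile):
        from dataclasses import replace

        for side in ("left", "right"):
            cfg = replace(sim_config, visible_side=side)
            rec = simulate_lift_instance(profile, "knuckle", 5.4, "lift", cfg, seed=2)
            assert select_side(rec.track) == side


class TestExtractSagittalJoints:
    def test_column_order_matches_coco_indices(self):
        T = 3
        kpts = np.zeros((T, pose_io.N_KEYPOINTS, 3))
        for j in range(pose_io.N_KEYPOINTS):
            kpts[:, j, 0] = 10.0 * j
            kpts[:, j, 1] = 100.0 + j
            kpts[:, j, 2] = 0.9
        track = pose_io.track_from_arrays(kpts, None, fps=30, video_id="o")
        joints = extract_sagittal_joints(track, "right")
        expected = [pose_io.COCO_INDEX[n] for n in
                    ("nose", "right_shoulder", "right_elbow", "right_wrist",
                     "right_hip", "right_knee", "right_ankle")]
        np.testing.assert_allclose(
            joints.positions[:, :, 0],
            np.tile(np.array(expected, float) * 10.0, (T, 1)),
        )

    def test_missing_joint_named(self):
        kpts = np.full((3, pose_io.N_KEYPOINTS, 3), 0.9)
        kpts[:, :, :2] = 50.0
        kpts[:, pose_io.COCO_INDEX["right_ankle"], 2] = 0.0
        track = pose_io.track_from_arrays(kpts, None, fps=30, video_id="m")
        with pytest.raises(KinematicsError, match="ankle"):
            extract_sagittal_joints(track, "right")


class TestNormalizePositions:
    def _joints(self, positions, bboxes):
        return SagittalJoints(side="right", positions=np.asarray(positions, float),
                              bboxes=np.asarray(bboxes, float))

    def test_center_maps_to_origin(self):
        pos = np.full((3, 7, 2), [150.0, 200.0])
        bboxes = np.tile([100.0, 100.0, 100.0, 200.0], (3, 1))  # center (150, 200)
        r = normalize_positions(self._joints(pos, bboxes))
        np.testing.assert_allclose(r, 0.0)

    def test_offset_scaled_by_max_height(self):
        pos = np.zeros((3, 7, 2))
        pos[:, 0] = (1060.0, 540.0)
        bboxes = np.tile([760.0, 340.0, 400.0, 400.0], (3, 1))  # center (960, 540)
        r = normalize_positions(self._joints(pos, bboxes))
        np.testing.assert_allclose(r[:, 0], 0.25)  # (1060-960)/400
        np.testing.assert_allclose(r[:, 1], 0.0)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 500, (4, 7, 2))
        bboxes = np.column_stack([
            rng.uniform(0, 100, 4), rng.uniform(0, 100, 4),
            rng.uniform(50, 200, 4), rng.uniform(100, 300, 4),
        ])
        r = normalize_positions(self._joints(pos, bboxes))
        s, tx, ty = 2.0, 50.0, -30.0
        pos2 = pos * s + [tx, ty]
        bboxes2 = np.column_stack([
            bboxes[:, 0] * s + tx, bboxes[:, 1] * s + ty,
            bboxes[:, 2] * s, bboxes[:, 3] * s,
        ])
        r2 = normalize_positions(self._joints(pos2, bboxes2))
        np.testing.assert_allclose(r2, r, atol=1e-9)


class TestComputeAngles:
    def _single_frame(self, coords):
        pos = np.tile(np.asarray(coords, float), (3, 1, 1))
        bboxes = np.tile([0.0, 0.0, 10.0, 10.0], (3, 1))
        return SagittalJoints(side="right", positions=pos, bboxes=bboxes)

    # joint order: head, shoulder, elbow, wrist, hip, knee, ankle
    def test_straight_arm_gives_pi(self):
        coords = [(5, -1), (0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        ang = compute_angles(self._single_frame(coords))
        np.testing.assert_allclose(ang[:, 1], np.pi)  # elbow angle

    def test_right_angle_elbow(self):
        coords = [(5, -1), (0, 0), (0, 1), (1, 1), (1, 0), (1, 1.5), (1, 2)]
        ang = compute_angles(self._single_frame(coords))
        np.testing.assert_allclose(ang[:, 1], np.pi / 2)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(-3, 3, (5, 7, 2))
        bboxes = np.tile([0.0, 0.0, 10.0, 10.0], (5, 1))
        joints = SagittalJoints(side="left", positions=pos, bboxes=bboxes)
        ang = compute_angles(joints)
        defs = [(0, 1, 2), (1, 2, 3), (2, 1, 4), (1, 4, 5), (4, 5, 6)]
        for t in range(5):
            for col, (a, v, b) in enumerate(defs):
                u, w = pos[t, a] - pos[t, v], pos[t, b] - pos[t, v]
                expected = np.arccos(np.clip(
                    u @ w / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1))
                assert abs(ang[t, col] - expected) < 1e-9

    def test_angles_within_range(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-10, 10, (20, 7, 2))
        bboxes = np.tile([0.0, 0.0, 10.0, 10.0], (20, 1))
        ang = compute_angles(SagittalJoints(side="right", positions=pos, bboxes=bboxes))
        assert (ang >= 0).all() and (ang <= np.pi).all()

    def test_degenerate_first_frame_rejected(self):
        coords = [(0, 0), (0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        with pytest.raises(KinematicsError, match="frame 0"):
            compute_angles(self._single_frame(coords))

    def test_degenerate_later_frame_carries_forward(self):
        pos = np.tile([(5.0, -1), (0, 0), (0, 1), (1, 1), (1, 0), (1, 1.5), (1, 2)], (3, 1, 1))
        pos[2, 0] = pos[2, 1]  # head collapses onto shoulder at frame 2
        bboxes = np.tile([0.0, 0.0, 10.0, 10.0], (3, 1))
        ang = compute_angles(SagittalJoints(side="right", positions=pos, bboxes=bboxes))
        assert ang[2, 0] == ang[1, 0]


class TestComputeDerivatives:
    def test_constant_signal(self):
        r = np.ones((6, 14)) * 3.0
        v, a = compute_derivatives(r)
        np.testing.assert_allclose(v, 0.0)
        np.testing.assert_allclose(a, 0.0)

    def test_linear_motion(self):
        t = np.arange(7.0)
        r = np.zeros((7, 2))
        r[:, 0] = t
        v, a = compute_derivatives(r)
        np.testing.assert_allclose(v[:, 0], 1.0)
        np.testing.assert_allclose(a[1:-1, 0], 0.0)

    def test_quadratic_oracle(self):
        t = np.arange(9.0)
        r = np.zeros((9, 2))
        r[:, 0] = t**2
        v, a = compute_derivatives(r)
        np.testing.assert_allclose(v[1:-1, 0], 2 * t[1:-1])
        np.testing.assert_allclose(a[1:-1, 0][1:-1], 2.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(8, 14)), rng.normal(size=(8, 14))
        vx, _ = compute_derivatives(x)
        vy, _ = compute_derivatives(y)
        vsum, _ = compute_derivatives(x + y)
        np.testing.assert_allclose(vsum, vx + vy, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(KinematicsError):
            compute_derivatives(np.zeros((2, 14)))


class TestAssembleFeatures:
    def test_width_and_length(self, lift_record):
        f = assemble_features(lift_record)
        assert f.values.shape == (len(lift_record.track), 47)

    def test_layout_slices(self, lift_record):
        f = assemble_features(lift_record)
        side = select_side(lift_record.track)
        joints = extract_sagittal_joints(lift_record.track, side)
        np.testing.assert_array_equal(f.values[:, ANG], compute_angles(joints))
        np.testing.assert_array_equal(f.values[:, POS], normalize_positions(joints))

    def test_similarity_invariance_of_full_features(self, lift_record):
        f = assemble_features(lift_record)
        kpts = lift_record.track.keypoint_array()
        s, tx, ty = 1.7, 33.0, -12.0
        kpts2 = kpts.copy()
        kpts2[:, :, 0] = kpts[:, :, 0] * s + tx
        kpts2[:, :, 1] = kpts[:, :, 1] * s + ty
        track2 = pose_io.track_from_arrays(
            kpts2, None, fps=lift_record.track.fps, video_id="scaled",
        )
        from dataclasses import replace

        f2 = assemble_features(replace(lift_record, track=track2))
        np.testing.assert_allclose(f2.values, f.values, atol=1e-9)


class TestFlipFeatures:
    def test_involution(self, lift_record):
        f = assemble_features(lift_record)
        np.testing.assert_array_equal(flip_features(flip_features(f)).values, f.values)

    def test_angles_unchanged(self, lift_record):
        f = assemble_features(lift_record)
        np.testing.assert_array_equal(flip_features(f).values[:, ANG], f.values[:, ANG])

    def test_sign_mask_oracle(self):
        mask = np.ones(47)
        for start in (0, 19, 33):  # x columns of r, v, a slices
            mask[start:start + 14:2] = -1.0
        np.testing.assert_array_equal(FLIP_SIGN, mask)
        rng = np.random.default_rng(5)
        f = FeatureSequence(values=rng.normal(size=(6, 47)), fps=30.0)
        np.testing.assert_array_equal(flip_features(f).values, f.values * mask)


class TestGaussianNoise:
    def test_sigma_zero_identity(self, lift_record):
        f = assemble_features(lift_record)
        np.testing.assert_array_equal(add_gaussian_noise(f, 0.0, seed=1).values, f.values)

    def test_seed_reproducibility(self, lift_record):
        f = assemble_features(lift_record)
        a = add_gaussian_noise(f, 0.05, seed=9)
        b = add_gaussian_noise(f, 0.05, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_sigma_rejected(self, lift_record):
        with pytest.raises(ValueError):
            add_gaussian_noise(assemble_features(lift_record), -0.1, seed=0)

    def test_large_sample_sd(self):
        rng = np.random.default_rng(0)
        f = FeatureSequence(values=rng.normal(size=(2200, 47)), fps=30.0)  # >1e5 entries
        noisy = add_gaussian_noise(f, 0.01, seed=3)
        sd = (noisy.values - f.values).std()
        assert 0.0095 <= sd <= 0.0105
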