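import math

import numpy as np
import pytest

from trackgeom.camera_model import GroundPoint, build_projection
from trackgeom.pose_metrics import (
    MetricsConfig,
    align_2d,
    apply_alignment,
    approx_3d_knee_error,
    detect_touchdown_frames,
    evaluate,
    facing_direction,
    knee_angle_2d,
    knee_angle_3d,
    knee_sensitivity,
    reprojection_error,
    rotate_lower_leg,
    rotate_to_facing,
    straighten_path,
)
from trackgeom.scene_model import JOINT_INDEX, Skeleton2D, Skeleton3D, project_skeleton
from trackgeom.synthetic_data import (
    GaitConfig,
    NoiseConfig,
    camera_looking_at,
    generate_runner,
    make_case,
)


def _skel2d_with(**joints):
    pts = np.tile(np.array([10.0, 10.0]), (17, 1)) + np.arange(17)[:, None]
    for name, xy in joints.items():
        pts[JOINT_INDEX[name]] = xy
    return Skeleton2D(pts)


@pytest.fixture(scope="module")
def runner_pose():
    frames, _ = generate_runner(n_frames=10)
    return frames[3][0]


class TestAlign2D:
    def test_recovers_known_scale_and_translation(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        proj2d = project_skeleton(placed, reference_projection)
        ref = Skeleton2D(2.0 * proj2d.joints + np.array([3.0, 4.0]))
        tf = align_2d(proj2d, ref)
        assert tf.scale == pytest.approx(2.0, abs=1e-12)
        assert tf.translation == pytest.approx((3.0, 4.0), abs=1e-9)
        aligned = apply_alignment(proj2d, tf)
        assert np.abs(aligned.joints - ref.joints).max() < 1e-9

    def test_identity_when_equal(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        proj2d = project_skeleton(placed, reference_projection)
        tf = align_2d(proj2d, proj2d)
        assert tf.scale == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(tf.translation) < 1e-9

    def test_closed_form_beats_random_probes(self, rng):
        """Brute-force oracle: no random (scale, translation) beats the
        closed-form least-squares residual."""
        p = Skeleton2D(rng.uniform(0, 500, (17, 2)))
        r = Skeleton2D(1.7 * p.joints + np.array([40.0, -20.0])
                       + rng.normal(0, 25.0, (17, 2)))
        tf = align_2d(p, r)
        best = float(np.sum((apply_alignment(p, tf).joints - r.joints) ** 2))
        scales = rng.uniform(0.1, 5.0, 10_000)
        txs = rng.uniform(-500, 500, 10_000)
        tys = rng.uniform(-500, 500, 10_000)
        probes = (
            np.einsum("i,jk->ijk", scales, p.joints)
            + np.stack([txs, tys], axis=1)[:, None, :]
        )
        residuals = np.sum((probes - r.joints[None]) ** 2, axis=(1, 2))
        assert best <= residuals.min() + 1e-9

    def test_degenerate_reference_rejected(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        proj2d = project_skeleton(placed, reference_projection)
        with pytest.raises(ValueError):
            align_2d(proj2d, Skeleton2D(np.full((17, 2), 7.0)))


class TestReprojectionError:
    def test_self_consistency_is_exactly_zero(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        ref = project_skeleton(placed, reference_projection)
        px, mm = reprojection_error(placed, reference_projection, ref)
        assert px == 0.0 and mm == 0.0

    def test_three_four_five_offset(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        proj2d = project_skeleton(placed, reference_projection)
        ref = Skeleton2D(proj2d.joints + np.array([3.0, 4.0]))
        px, mm = reprojection_error(placed, reference_projection, ref,
                                    athlete_height_mm=1800.0, align=False)
        assert px == pytest.approx(5.0, abs=1e-9)
        assert mm == pytest.approx(5.0 * 1800.0 / ref.height, rel=1e-9)

    def test_jitter_matches_rayleigh_mean(self, reference_projection, rng):
        """2 px Gaussian jitter: mean per-joint offset ~ sigma sqrt(pi/2),
        within 5% over 1000 frames (alignment removes 3 of 34 dof)."""
        frames, _ = generate_runner(n_frames=1000)
        sigma = 2.0
        errs = []
        for skel, _ in frames:
            placed = skel.translated([30.0, 3.0, 0.0] - skel.joints[skel.ground_contact_index()])
            ref = Skeleton2D(
                project_skeleton(placed, reference_projection).joints
                + rng.normal(0, sigma, (17, 2))
            )
            px, _ = reprojection_error(placed, reference_projection, ref)
            errs.append(px)
        prediction = sigma * math.sqrt(math.pi / 2)
        assert np.mean(errs) == pytest.approx(prediction, rel=0.05)


class TestKneeAngles:
    def test_straight_leg_is_180(self):
        s = _skel2d_with(left_hip=(0, 0), left_knee=(0, 1), left_ankle=(0, 2))
        assert knee_angle_2d(s, "left") == pytest.approx(180.0)

    def test_right_angle(self):
        s = _skel2d_with(left_hip=(0, 0), left_knee=(0, 1), left_ankle=(1, 1))
        assert knee_angle_2d(s, "left") == pytest.approx(90.0)

    def test_oblique_angle_matches_dot_product_oracle(self):
        hip, knee, ankle = (0.0, 0.0), (1.0, 0.0), (2.0, math.tan(math.radians(30.0)))
        s = _skel2d_with(left_hip=hip, left_knee=knee, left_ankle=ankle)
        a = np.asarray(hip) - np.asarray(knee)
        b = np.asarray(ankle) - np.asarray(knee)
        oracle = math.degrees(math.acos(a @ b / (np.linalg.norm(a) * np.linalg.norm(b))))
        assert knee_angle_2d(s, "left") == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(150.0, abs=1e-9)

    def test_coincident_joints_rejected(self):
        s = _skel2d_with(left_hip=(1, 1), left_knee=(1, 1), left_ankle=(2, 2))
        with pytest.raises(ValueError):
            knee_angle_2d(s, "left")

    def test_invariance_under_similarity_transform(self, runner_pose, reference_projection):
        placed = runner_pose.translated([30.0, 3.0, 0.0] - runner_pose.joints[runner_pose.ground_contact_index()])
        s = project_skeleton(placed, reference_projection)
        a = knee_angle_2d(s, "right")
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        s2 = Skeleton2D(3.0 * s.joints @ R.T + np.array([40.0, -7.0]))
        assert knee_angle_2d(s2, "right") == pytest.approx(a, abs=1e-9)


@pytest.fixture(scope="module")
def bent_pose():
    """A canonical sagittal-plane leg: thigh forward, shank back (~100 deg
    knee), embedded in an otherwise neutral 17-joint skeleton."""
    frames, _ = generate_runner(n_frames=1)
    joints = frames[0][0].joints.copy()
    y = joints[JOINT_INDEX["left_hip"], 1]
    joints[JOINT_INDEX["left_hip"]] = [0.0, y, 0.90]
    joints[JOINT_INDEX["left_knee"]] = [0.25, y, 0.50]
    joints[JOINT_INDEX["left_ankle"]] = [0.05, y, 0.12]
    return Skeleton3D(joints)


class TestApprox3DKnee:

    def _view_from(self, pose, view_deg, dist=40.0):
        """Camera orbiting the knee: 0 = sagittal (side-on), 90 = frontal."""
        knee = pose.joint("left_knee")
        ang = math.radians(view_deg)
        pos = (knee[0] + dist * math.sin(ang), knee[1] - dist * math.cos(ang), 2.0)
        return build_projection(camera_looking_at(pos, (knee[0], knee[1]), 10.0))

    def test_sagittal_sensitivity_near_one(self, bent_pose):
        s = knee_sensitivity(bent_pose, self._view_from(bent_pose, 0.0), "left")
        assert 0.9 <= s <= 1.1

    def test_sensitivity_decreases_toward_frontal(self, bent_pose):
        vals = [
            knee_sensitivity(bent_pose, self._view_from(bent_pose, v), "left")
            for v in range(0, 81, 10)
        ]
        # monotone up to a tiny perspective wobble near the sagittal view
        assert all(b < a + 5e-3 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.5 * vals[0]

    def test_estimate_matches_true_3d_change(self, bent_pose):
        """A known 5 deg 3D flexion viewed 40 deg off-sagittal is recovered
        within 20% by scaling the measured 2D error."""
        proj = self._view_from(bent_pose, 40.0)
        true_delta = 5.0
        pert = rotate_lower_leg(bent_pose, "left", true_delta)
        true_3d_change = abs(knee_angle_3d(pert, "left") - knee_angle_3d(bent_pose, "left"))
        err2d = abs(
            knee_angle_2d(project_skeleton(pert, proj), "left")
            - knee_angle_2d(project_skeleton(bent_pose, proj), "left")
        )
        est, capped = approx_3d_knee_error(bent_pose, proj, err2d, "left")
        assert not capped
        assert est == pytest.approx(true_3d_change, rel=0.2)

    def test_degenerate_view_is_capped(self, bent_pose):
        proj = self._view_from(bent_pose, 89.9)
        est, capped = approx_3d_knee_error(bent_pose, proj, 5.0, "left")
        assert capped and est == pytest.approx(5.0 / 0.05)


class TestTouchdownDetection:
    def test_scripted_contacts_recovered(self, runner_case):
        seq = [s2 for (_, s2) in runner_case.skeletons]
        detected = detect_touchdown_frames(seq)
        assert detected
        for d in detected:
            assert min(abs(d - t) for t in runner_case.touchdown_frames) <= 1
        for t in runner_case.touchdown_frames:
            assert min(abs(d - t) for d in detected) <= 1

    def test_stationary_sequence_collapses_to_midpoint(self, runner_case):
        frame = runner_case.skeletons[5][1]
        out = detect_touchdown_frames([frame] * 21)
        assert out == [10]

    def test_airborne_only_sequence_empty(self, runner_case, rng):
        # strictly monotone ankle motion: no low-velocity local maximum
        base = runner_case.skeletons[0][1].joints
        seq = []
        for i in range(20):
            j = base.copy()
            j[:, 1] += 30.0 * i  # continuously rising/falling ankles
            seq.append(Skeleton2D(j))
        assert detect_touchdown_frames(seq) == []

    def test_short_sequence_rejected(self, runner_case):
        with pytest.raises(ValueError):
            detect_touchdown_frames([runner_case.skeletons[0][1]] * 3)


class TestStraightenPath:
    def test_collinear_anchors_unchanged(self, runner_case):
        skels = [s for s, _ in runner_case.skeletons[:10]]
        anchors = [GroundPoint(xy=(2.0 * i, 4.27)) for i in range(10)]
        out_s, out_a = straighten_path(skels, anchors)
        for a, b in zip(skels, out_s):
            assert np.abs(a.joints - b.joints).max() < 1e-12

    def test_arc_anchors_straightened_by_chord_distance(self, runner_case):
        """Anchors on a circular arc land on the TLS line, each moved by its
        analytic sagitta-like offset."""
        skels = [s for s, _ in runner_case.skeletons[:9]]
        R, n = 200.0, 9
        thetas = np.linspace(-0.2, 0.2, n)
        xs = R * np.sin(thetas)
        ys = R * (1 - np.cos(thetas))  # arc bulging in +y
        anchors = [GroundPoint(xy=(x, y)) for x, y in zip(xs, ys)]
        out_s, out_a = straighten_path(skels, anchors)
        pts = np.array([a.xy for a in out_a])
        rel = pts - pts.mean(axis=0)
        _, sv, _ = np.linalg.svd(rel, full_matrices=False)
        assert sv[1] < 1e-9  # perfectly collinear output
        moved = np.linalg.norm(pts - np.column_stack([xs, ys]), axis=1)
        # analytic: distance from each arc point to the TLS line of the arc
        line_y = ys.mean()
        analytic = np.abs(ys - line_y)  # TLS line of a symmetric arc is y = mean
        np.testing.assert_allclose(moved, analytic, atol=1e-9)

    def test_internal_geometry_preserved(self, runner_case):
        skels = [s for s, _ in runner_case.skeletons[:5]]
        anchors = [GroundPoint(xy=(i * 2.0, 0.1 * i * i)) for i in range(5)]
        out_s, _ = straighten_path(skels, anchors)
        for a, b in zip(skels, out_s):
            da = a.joints - a.joints[0]
            db = b.joints - b.joints[0]
            assert np.abs(da - db).max() < 1e-9

    def test_coincident_anchors_warn_and_pass_through(self, runner_case):
        skels = [s for s, _ in runner_case.skeletons[:3]]
        anchors = [GroundPoint(xy=(1.0, 1.0))] * 3
        with pytest.warns(UserWarning):
            out_s, _ = straighten_path(skels, anchors)
        assert np.abs(out_s[0].joints - skels[0].joints).max() == 0.0


class TestRotateToFacing:
    def test_already_facing_unchanged(self, runner_pose):
        out = rotate_to_facing(runner_pose, (1.0, 0.0))
        assert np.abs(out.joints - runner_pose.joints).max() < 1e-9

    def test_quarter_turn_preserves_distances(self, runner_pose):
        out = rotate_to_facing(runner_pose, (0.0, 1.0))
        np.testing.assert_allclose(facing_direction(out), [0.0, 1.0], atol=1e-9)
        d_in = np.linalg.norm(runner_pose.joints[:, None] - runner_pose.joints[None], axis=-1)
        d_out = np.linalg.norm(out.joints[:, None] - out.joints[None], axis=-1)
        assert np.abs(d_in - d_out).max() < 1e-9

    def test_random_yaws_recovered(self, runner_pose, rng):
        for _ in range(1000):
            f = rng.normal(size=2)
            f /= np.linalg.norm(f)
            out = rotate_to_facing(runner_pose, f)
            assert np.linalg.norm(facing_direction(out) - f) < 1e-9


class TestEvaluate:
    def test_perfect_triples_give_zero_metrics(self, runner_case):
        cam = runner_case.camera_truth
        triples = [
            (runner_case.observed_2d[i], runner_case.predicted_3d[i], cam)
            for i in runner_case.touchdown_frames
        ]
        rep = evaluate(triples)
        assert rep.reproj_px < 1e-4
        assert rep.reproj_mm < 1e-3
        assert rep.knee2d_deg < 1e-6
        assert rep.knee3d_approx_deg < 1e-6

    def test_injected_knee_bias_recovered_sagittally(self):
        """5 deg of knee flexion bias measured within 10% from a side-on view."""
        cam = camera_looking_at((2.5, -40.0, 3.0), (2.5, 4.27), 12.0)
        case = make_case(cam, noise=NoiseConfig(knee_bias_deg=5.0),
                         n_frames=25, render_image=False)
        triples = [
            (case.observed_2d[i], case.predicted_3d[i], cam)
            for i in case.touchdown_frames
        ]
        rep = evaluate(triples)
        assert rep.knee2d_deg == pytest.approx(5.0, rel=0.10)

    def test_rotation_knowledge_reduces_error_under_yaw_drift(self):
        cam = camera_looking_at((-20.0, -25.0, 8.0), (0.0, 4.27), 12.0)
        case = make_case(cam, noise=NoiseConfig(yaw_amp_deg=8.0),
                         n_frames=80, render_image=False)
        triples = [
            (case.observed_2d[i], case.predicted_3d[i], cam)
            for i in case.touchdown_frames
        ]
        base = evaluate(triples)
        rot = evaluate(triples, strategy="rotation")
        assert rot.reproj_px < base.reproj_px
        assert rot.knee3d_approx_deg < base.knee3d_approx_deg

    def test_movement_knowledge_reduces_error_on_curved_predictions(self):
        cam = camera_looking_at((-20.0, -25.0, 8.0), (0.0, 4.27), 12.0)
        case = make_case(cam, noise=NoiseConfig(path_bend_m=1.0),
                         n_frames=80, render_image=False)
        triples = [
            (case.observed_2d[i], case.predicted_3d[i], cam)
            for i in case.touchdown_frames
        ]
        base = evaluate(triples)
        mov = evaluate(triples, strategy="movement")
        assert mov.reproj_px < base.reproj_px

    def test_unknown_strategy_rejected(self, runner_case):
        cam = runner_case.camera_truth
        triples = [(runner_case.observed_2d[0], runner_case.predicted_3d[0], cam)]
        with pytest.raises(ValueError):
            evaluate(triples, strategy="telepathy")
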