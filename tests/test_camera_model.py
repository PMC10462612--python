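import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackgeom.camera_model import (
    AtInfinity,
    BehindCameraError,
    CameraParams,
    InvalidCameraError,
    NoIntersectionError,
    build_projection,
    camera_from_dict,
    camera_to_dict,
    load_camera,
    project_points,
    ray_trace_to_ground,
    save_camera,
    vanishing_point_of_direction,
)


def _oracle_projection(az, el, roll, fov, pos, size):
    """Hand-composed K[R|t] from elementary rotations, independent of the
    implementation's composition helpers."""
    w, h = size

    def rx(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def rz(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    base = np.array([[0.0, -1.0, 0.0], [0.0, 0.0, -1.0], [1.0, 0.0, 0.0]])
    R = rz(math.radians(roll)) @ rx(math.radians(el)) @ base @ rz(-math.radians(az))
    f = (w / 2) / math.tan(math.radians(fov) / 2)
    K = np.array([[f, 0, w / 2], [0, f, h / 2], [0, 0, 1.0]])
    t = -R @ np.asarray(pos, float)
    return K @ np.hstack([R, t[:, None]])


class TestBuildProjection:
    def test_identity_pose_aligns_optical_axis_with_lanes(self):
        cam = CameraParams(azimuth=0, elevation=0, roll=0, fov=20, position=(0, 0, 0))
        proj = build_projection(cam)
        # optical axis (third row of R in world coords) is the lane direction
        np.testing.assert_allclose(proj.R[2], [1, 0, 0], atol=1e-15)

    def test_rotation_orthonormality(self, rng):
        for _ in range(50):
            cam = CameraParams(
                azimuth=rng.uniform(-89, 89), elevation=rng.uniform(0, 80),
                roll=rng.uniform(-30, 30), fov=rng.uniform(5, 170),
                position=tuple(rng.uniform(-50, 50, 3)),
            )
            R = build_projection(cam).R
            assert np.abs(R @ R.T - np.eye(3)).max() < 1e-12
            assert abs(np.linalg.det(R) - 1) < 1e-12

    def test_matches_hand_composed_oracle(self):
        cam = CameraParams(azimuth=30, elevation=10, roll=0, fov=20,
                           position=(0, -12, 6), image_size=(1280, 720))
        P = build_projection(cam).P
        P_oracle = _oracle_projection(30, 10, 0, 20, (0, -12, 6), (1280, 720))
        assert np.abs(P - P_oracle).max() < 1e-12 * max(1.0, np.abs(P_oracle).max())

    @pytest.mark.parametrize("fov", [0.0, -5.0, 180.0, 200.0])
    def test_degenerate_fov_rejected(self, fov):
        with pytest.raises(InvalidCameraError):
            CameraParams(azimuth=0, elevation=0, roll=0, fov=fov, position=(0, 0, 0))


class TestProjectPoints:
    def test_view_target_hits_principal_point(self, reference_camera, reference_projection):
        # the point where the optical axis pierces the ground
        gp = ray_trace_to_ground(reference_camera.principal_point, reference_projection)
        px = project_points(gp.xyz, reference_projection)
        np.testing.assert_allclose(px, reference_camera.principal_point, atol=1e-9)

    def test_zoom_in_moves_points_radially_outward(self, reference_camera):
        wide = build_projection(reference_camera)
        narrow = build_projection(
            CameraParams(**{**camera_to_dict_kwargs(reference_camera), "fov": 10.0})
        )
        pt = np.array([30.0, 3.0, 1.0])
        c = reference_camera.principal_point
        r_wide = np.linalg.norm(project_points(pt, wide) - c)
        r_narrow = np.linalg.norm(project_points(pt, narrow) - c)
        assert r_narrow > r_wide

    def test_pixel_matches_oracle_matrix(self, reference_projection):
        P_oracle = _oracle_projection(30, 10, 0, 20, (0, -12, 6), (1280, 720))
        X = np.array([25.0, 3.3, 1.1, 1.0])
        u, v, w = P_oracle @ X
        expected = np.array([u / w, v / w])
        got = project_points(X[:3], reference_projection)
        assert np.linalg.norm(got - expected) < 1e-9

    def test_behind_camera_flagged(self, reference_projection):
        with pytest.raises(BehindCameraError):
            project_points(np.array([-100.0, -12.0, 6.0]), reference_projection)


class TestVanishingPoint:
    def test_optical_axis_projects_to_centre(self, reference_camera, reference_projection):
        d = reference_projection.R[2]  # optical axis in world coords
        vp = vanishing_point_of_direction(d, reference_projection)
        np.testing.assert_allclose(vp, reference_camera.principal_point, atol=1e-9)

    def test_translation_invariance(self, rng):
        """Moving the camera without turning it keeps every vanishing point."""
        for _ in range(1000):
            az, el, roll = rng.uniform(-80, 80), rng.uniform(1, 60), rng.uniform(-20, 20)
            fov = rng.uniform(5, 120)
            d = rng.normal(size=3)
            p1 = build_projection(CameraParams(azimuth=az, elevation=el, roll=roll,
                                               fov=fov, position=tuple(rng.uniform(-50, 50, 3))))
            p2 = build_projection(CameraParams(azimuth=az, elevation=el, roll=roll,
                                               fov=fov, position=tuple(rng.uniform(-50, 50, 3))))
            v1 = vanishing_point_of_direction(d, p1)
            v2 = vanishing_point_of_direction(d, p2)
            if isinstance(v1, AtInfinity):
                assert isinstance(v2, AtInfinity)
                continue
            assert np.linalg.norm(v1 - v2) < 1e-9

    def test_far_point_extrapolation_oracle(self, reference_projection):
        """The analytic VP agrees with Richardson extrapolation of projected
        far lane points (error of a finite point falls off as 1/x)."""
        p5 = project_points(np.array([1e5, 0, 0]), reference_projection)
        p6 = project_points(np.array([1e6, 0, 0]), reference_projection)
        extrapolated = p6 + (p6 - p5) / 9.0
        vp = vanishing_point_of_direction(np.array([1.0, 0, 0]), reference_projection)
        assert np.linalg.norm(vp - extrapolated) < 1e-3

    def test_direction_parallel_to_image_plane_at_infinity(self):
        cam = CameraParams(azimuth=0, elevation=0, roll=0, fov=20, position=(0, 0, 5))
        vp = vanishing_point_of_direction(np.array([0.0, 1.0, 0.0]), build_projection(cam))
        assert isinstance(vp, AtInfinity)

    def test_zoom_ray_collinearity(self, reference_camera):
        """Varying fov slides the lane VP along the fixed ray through the
        principal point."""
        c = reference_camera.principal_point
        vps = []
        for fov in np.linspace(5, 60, 12):
            proj = build_projection(
                CameraParams(**{**camera_to_dict_kwargs(reference_camera), "fov": float(fov)})
            )
            vps.append(vanishing_point_of_direction(np.array([1.0, 0, 0]), proj) - c)
        ref = vps[0] / np.linalg.norm(vps[0])
        for v in vps[1:]:
            cross = abs(ref[0] * v[1] - ref[1] * v[0]) / max(np.linalg.norm(v), 1.0)
            assert cross < 1e-6
            assert v @ ref > 0  # same side of the centre

    def test_horizon_horizontal_at_zero_roll(self, rng):
        for _ in range(200):
            proj = build_projection(CameraParams(
                azimuth=rng.uniform(-80, 80), elevation=rng.uniform(1, 60), roll=0.0,
                fov=rng.uniform(5, 120), position=tuple(rng.uniform(-50, 50, 3)),
            ))
            v_lane = vanishing_point_of_direction(np.array([1.0, 0, 0]), proj)
            v_cross = vanishing_point_of_direction(np.array([0.0, 1, 0]), proj)
            assert abs(v_lane[1] - v_cross[1]) < 1e-6


class TestRayTrace:
    def test_known_ground_point_round_trip(self, reference_projection):
        px = project_points(np.array([3.0, 2.44, 0.0]), reference_projection)
        gp = ray_trace_to_ground(px, reference_projection)
        np.testing.assert_allclose(gp.xy, (3.0, 2.44), atol=1e-9)

    def test_horizon_pixel_has_no_intersection(self, reference_camera, reference_projection):
        v_lane = vanishing_point_of_direction(np.array([1.0, 0, 0]), reference_projection)
        with pytest.raises(NoIntersectionError):
            ray_trace_to_ground(v_lane, reference_projection)

    def test_project_after_ray_trace_is_identity(self, rng):
        """Ground round trip over random cameras and pixels below the horizon."""
        checked = 0
        while checked < 1000:
            proj = build_projection(CameraParams(
                azimuth=rng.uniform(-80, 80), elevation=rng.uniform(2, 60), roll=0.0,
                fov=rng.uniform(10, 90),
                position=(rng.uniform(-40, 40), rng.uniform(-40, -5), rng.uniform(2, 15)),
            ))
            px = rng.uniform([0, 0], [1280, 720])
            try:
                gp = ray_trace_to_ground(px, proj)
            except NoIntersectionError:
                continue
            back = project_points(gp.xyz, proj)
            assert np.linalg.norm(back - px) < 1e-6
            checked += 1


@settings(max_examples=150, derandomize=True)
@given(
    az=st.floats(-80, 80),
    el=st.floats(2, 60),
    fov=st.floats(8, 90),
    cy=st.floats(-45, -5),
    cz=st.floats(2, 15),
    px=st.floats(50, 1230),
    py=st.floats(50, 670),
)
def test_ground_round_trip_property(az, el, fov, cy, cz, px, py):
    """project(ray_trace(pixel)) == pixel for any pixel below the horizon."""
    proj = build_projection(
        CameraParams(azimuth=az, elevation=el, roll=0.0, fov=fov, position=(0.0, cy, cz))
    )
    try:
        gp = ray_trace_to_ground((px, py), proj)
    except NoIntersectionError:
        return  # pixel on/above the horizon: correctly refused
    back = project_points(gp.xyz, proj)
    assert np.linalg.norm(back - np.array([px, py])) < 1e-6


def camera_to_dict_kwargs(cam):
    return dict(azimuth=cam.azimuth, elevation=cam.elevation, roll=cam.roll,
                fov=cam.fov, position=cam.position, image_size=cam.image_size)


def test_camera_file_round_trip(tmp_path, reference_camera):
    for ext in (".yaml", ".json"):
        path = tmp_path / f"cam{ext}"
        save_camera(reference_camera, path)
        loaded = load_camera(path)
        assert loaded == reference_camera
    assert camera_from_dict(camera_to_dict(reference_camera)) == reference_camera
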