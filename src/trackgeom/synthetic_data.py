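"""Synthetic fixtures: rendered lane images and articulated runner sequences.

Everything downstream is testable against these fixtures without any
external footage: a ground plane ruled with parallel lane lines 1.22 m
apart, a pan/tilt/zoom pinhole camera in the stands, and a 17-joint
runner advancing down the home stretch with a parametric (not
biomechanical) gait.  Each case carries its exact ground truth: the
camera, the analytic image lines of every lane, the analytic lane
vanishing point, and paired 2D/3D skeletons where the 2D joints are the
exact projections of the 3D ones.

An optional radial-distortion knob bends the rendered image only; the
analytic truth is recorded pre-distortion, mirroring the pinhole scope
of the calibration path (distortion exists for robustness experiments,
never as a modelled quantity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .camera_model import (
    CameraParams,
    GroundPoint,
    ProjectionMatrix,
    build_projection,
    vanishing_point_of_direction,
    AtInfinity,
)
from .lane_detection import ImageLine
from .scene_model import (
    JOINT_INDEX,
    Skeleton2D,
    Skeleton3D,
    TrackScene,
    lane_lines_3d,
)

__all__ = [
    "RenderStyle",
    "DistortionModel",
    "GaitConfig",
    "NoiseConfig",
    "SyntheticCase",
    "render_track",
    "generate_runner",
    "make_case",
    "analytic_lane_lines",
    "analytic_v0",
    "camera_looking_at",
    "sample_broadcast_camera",
]


@dataclass(frozen=True)
class RenderStyle:
    """Appearance knobs of the lane renderer."""

    line_width_px: float = 3.0
    line_brightness: float = 0.95
    background_base: float = 0.35
    background_gradient: float = 0.10
    noise_sigma: float = 0.02


@dataclass(frozen=True)
class DistortionModel:
    """Radial lens distortion (render-time only); k1 = k2 = 0 is pinhole."""

    k1: float = 0.0
    k2: float = 0.0

    @property
    def is_pinhole(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0


@dataclass(frozen=True)
class GaitConfig:
    """Parametric running gait (kinematic template, not a biomechanical model).

    Defaults emulate a fast runner on the home stretch: 7.2 m/s at a
    3.6 m full gait cycle (two 1.8 m steps, 2 cycles/s), 20% stance
    fraction, sampled at broadcast 50 fps.  The template pins the stance
    foot to the ground for the whole stance, so the stride/leg geometry
    is chosen to stay within leg reach (no heel-off is modelled).
    """

    speed: float = 7.2            # m/s along +x
    cycle_length: float = 3.6     # metres per full gait cycle (two steps)
    duty: float = 0.2             # stance fraction of the cycle
    fps: float = 50.0
    lift_height: float = 0.25     # swing-phase foot clearance, metres
    runner_y: float = 4.27        # lane-4 centre (3.5 lane widths)
    pelvis_height: float = 0.87
    bounce: float = 0.03          # vertical pelvis oscillation amplitude
    thigh: float = 0.50
    shank: float = 0.48
    hip_half: float = 0.10
    shoulder_half: float = 0.20
    torso: tuple[float, float, float, float] = (0.15, 0.20, 0.20, 0.15)
    upper_arm: float = 0.30
    forearm: float = 0.28
    arm_amp: float = 0.7          # arm swing amplitude, radians
    elbow_bend: float = 1.3       # fixed elbow flexion, radians


@dataclass(frozen=True)
class NoiseConfig:
    """Corruptions emulating HPE error modes.

    ``jitter_2d_px`` perturbs the observed 2D joints (Gaussian, per
    coordinate); ``knee_bias_deg`` flexes each predicted knee by a fixed
    bias; ``yaw_amp_deg`` yaws predicted skeletons linearly across the
    sequence; ``path_bend_m`` bows the predicted ground path into an arc
    and yaws each skeleton along the arc's tangent - the
    curved-trajectory failure mode of lifted 3D sequences under a
    panning camera.
    """

    jitter_2d_px: float = 0.0
    knee_bias_deg: float = 0.0
    yaw_amp_deg: float = 0.0
    path_bend_m: float = 0.0


@dataclass(frozen=True)
class SyntheticCase:
    """One fully-specified fixture with exact ground truth.

    ``skeletons`` pairs each 3D skeleton with its *exact* projection under
    ``camera_truth``; ``observed_2d`` / ``predicted_3d`` carry the
    noise-corrupted counterparts (identical to the clean ones when the
    noise config is all-zero).
    """

    camera_truth: CameraParams
    image: np.ndarray | None
    lane_lines_true: tuple[ImageLine, ...]
    v0_true: tuple[float, float] | None  # None: camera looks across the lanes
    skeletons: tuple[tuple[Skeleton3D, Skeleton2D], ...]
    anchors: tuple[GroundPoint, ...]
    touchdown_frames: tuple[int, ...]
    observed_2d: tuple[Skeleton2D, ...]
    predicted_3d: tuple[Skeleton3D, ...]
    seed: int


# ---------------------------------------------------------------------------
# Broadcast-style camera placement


def camera_looking_at(
    position, target_xy, fov: float, image_size=(1280, 720)
) -> CameraParams:
    """Pinhole camera at ``position`` whose principal ray meets the ground
    at ``target_xy`` (roll 0).  With the target on x = 0 the camera obeys
    the same view-target convention the geometry search uses, making
    recovered and true positions directly comparable."""
    pos = np.asarray(position, dtype=float)
    tgt = np.array([target_xy[0], target_xy[1], 0.0])
    d = tgt - pos
    az = math.degrees(math.atan2(d[1], d[0]))
    el = math.degrees(math.atan2(-d[2], math.hypot(d[0], d[1])))
    return CameraParams(
        azimuth=az, elevation=el, roll=0.0, fov=fov,
        position=tuple(pos), image_size=tuple(image_size),
    )


def sample_broadcast_camera(
    rng: np.random.Generator,
    scene: TrackScene = TrackScene(),
    image_size=(1280, 720),
    az_range=(15.0, 75.0),
    el_range=(3.0, 30.0),
    fov_range=(5.0, 40.0),
    x_range=(-55.0, 25.0),
    y_range=(-45.0, -12.0),
    z_range=(5.0, 12.0),
    grid_fill_range=(0.35, 0.8),
    min_lane_support_px: float = 300.0,
    max_tries: int = 1000,
) -> CameraParams:
    """Sample a ground-truth camera with realistic broadcast framing.

    The position is drawn from a stands-like box on the infield-opposite
    side, the view target sits on the track (x = 0), and the field of
    view is chosen so the lane grid fills a substantial fraction of the
    frame height - a PTZ operator zooms with distance, so fov and range
    are correlated, exactly as in real home-stretch footage.  Rejection
    sampling enforces the azimuth/elevation/fov ranges and that every
    lane line is visible with at least ``min_lane_support_px`` of
    in-image length.
    """
    w, h = image_size
    span_y = (scene.n_lanes - 1) * scene.lane_width
    for _ in range(max_tries):
        pos = np.array(
            [
                rng.uniform(*x_range),
                rng.uniform(*y_range),
                rng.uniform(*z_range),
            ]
        )
        yt = rng.uniform(0.3 * span_y, 0.7 * span_y)
        probe = camera_looking_at(pos, (0.0, yt), 20.0, image_size)
        if not (az_range[0] <= abs(probe.azimuth) <= az_range[1]):
            continue
        if not (el_range[0] <= probe.elevation <= el_range[1]):
            continue
        # pixel span of the grid at the probe fov scales ~linearly with
        # focal length; solve the fov that hits the desired frame fill
        proj = build_projection(probe)
        try:
            px = _project_all(
                np.array([[0.0, 0.0, 0.0], [0.0, span_y, 0.0]]), proj
            )
        except ValueError:
            continue
        span_px = float(np.linalg.norm(px[1] - px[0]))
        if span_px < 1.0:
            continue
        fill = rng.uniform(*grid_fill_range)
        focal = probe.focal_px * (fill * h) / span_px
        fov = math.degrees(2.0 * math.atan((w / 2.0) / focal))
        if not (fov_range[0] <= fov <= fov_range[1]):
            continue
        cam = camera_looking_at(pos, (0.0, yt), fov, image_size)
        lines = analytic_lane_lines(build_projection(cam), scene)
        if len(lines) < scene.n_lanes:
            continue
        if min(ln.support for ln in lines) < min_lane_support_px:
            continue
        return cam
    raise RuntimeError("could not sample a broadcast camera in the given ranges")


# ---------------------------------------------------------------------------
# Track rendering


def _clip_world_segment_to_front(p0, p1, proj: ProjectionMatrix, eps: float = 1e-3):
    """Clip a world segment to the half-space strictly in front of the camera."""
    hom = np.hstack([np.vstack([p0, p1]), np.ones((2, 1))]) @ proj.P.T
    w0, w1 = hom[0, 2], hom[1, 2]
    if w0 <= eps and w1 <= eps:
        return None
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    if w0 <= eps or w1 <= eps:
        # w is affine along the segment; find w = eps
        t = (eps - w0) / (w1 - w0)
        cut = a + t * (b - a)
        if w0 <= eps:
            a = cut
        else:
            b = cut
    return a, b


def _clip_to_box(p0, p1, w, h, margin=4.0):
    """Liang-Barsky clip of an image segment to the (expanded) image box."""
    x0, y0 = p0
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 + margin),
        (dx, w + margin - x0),
        (-dy, y0 + margin),
        (dy, h + margin - y0),
    ):
        if p == 0.0:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            t0 = max(t0, r)
        else:
            t1 = min(t1, r)
        if t0 > t1:
            return None
    a = np.array([x0 + t0 * dx, y0 + t0 * dy])
    b = np.array([x0 + t1 * dx, y0 + t1 * dy])
    return a, b


def analytic_lane_lines(proj: ProjectionMatrix, scene: TrackScene) -> tuple[ImageLine, ...]:
    """Exact image lines of the scene's lane lines (visible ones only)."""
    w, h = proj.image_size
    out = []
    for p0, p1 in lane_lines_3d(scene):
        seg = _clip_world_segment_to_front(p0, p1, proj)
        if seg is None:
            continue
        hom = np.hstack([np.vstack(seg), np.ones((2, 1))]) @ proj.P.T
        px = hom[:, :2] / hom[:, 2:3]
        if np.linalg.norm(px[1] - px[0]) < 1e-9:
            continue
        clipped = _clip_to_box(px[0], px[1], w, h)
        if clipped is None:
            continue
        mid = 0.5 * (clipped[0] + clipped[1])
        out.append(ImageLine(point=mid, direction=px[1] - px[0],
                             support=float(np.linalg.norm(clipped[1] - clipped[0]))))
    return tuple(out)


def analytic_v0(proj: ProjectionMatrix) -> tuple[float, float] | None:
    """Exact lane vanishing point, or None when it lies at infinity
    (camera looking exactly across the lanes)."""
    vp = vanishing_point_of_direction(np.array([1.0, 0.0, 0.0]), proj)
    if isinstance(vp, AtInfinity):
        return None
    return (float(vp[0]), float(vp[1]))


def _draw_segment_aa(img: np.ndarray, a, b, width: float, brightness: float) -> None:
    """Additively rasterise an anti-aliased segment of the given width."""
    h, w = img.shape
    halfw = width / 2.0
    pad = int(math.ceil(halfw + 1.5))
    x_min = max(0, int(math.floor(min(a[0], b[0]))) - pad)
    x_max = min(w - 1, int(math.ceil(max(a[0], b[0]))) + pad)
    y_min = max(0, int(math.floor(min(a[1], b[1]))) - pad)
    y_max = min(h - 1, int(math.ceil(max(a[1], b[1]))) + pad)
    if x_min > x_max or y_min > y_max:
        return
    xs = np.arange(x_min, x_max + 1)
    ys = np.arange(y_min, y_max + 1)
    X, Y = np.meshgrid(xs, ys)
    d = b - a
    L2 = float(d @ d)
    if L2 == 0:
        return
    t = ((X - a[0]) * d[0] + (Y - a[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    px = a[0] + t * d[0]
    py = a[1] + t * d[1]
    dist = np.hypot(X - px, Y - py)
    cov = np.clip(halfw + 0.5 - dist, 0.0, 1.0)
    patch = img[y_min : y_max + 1, x_min : x_max + 1]
    np.maximum(patch, cov * brightness, out=patch)


def _apply_radial_distortion(img: np.ndarray, cam: CameraParams, dist: DistortionModel) -> np.ndarray:
    """Warp a pinhole render through a radial lens model.

    Output pixels are distorted coordinates; the pinhole source location is
    recovered by fixed-point inversion of x_d = x_u (1 + k1 r^2 + k2 r^4)
    in focal-normalised coordinates.
    """
    if dist.is_pinhole:
        return img
    h, w = img.shape
    f = cam.focal_px
    cx, cy = w / 2.0, h / 2.0
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xd = (X - cx) / f
    yd = (Y - cy) / f
    xu, yu = xd.copy(), yd.copy()
    for _ in range(8):
        r2 = xu * xu + yu * yu
        factor = 1.0 + dist.k1 * r2 + dist.k2 * r2 * r2
        xu = xd / factor
        yu = yd / factor
    rows = yu * f + cy
    cols = xu * f + cx
    return map_coordinates(img, [rows, cols], order=1, mode="nearest")


def render_track(
    camera: CameraParams,
    scene: TrackScene = TrackScene(),
    style: RenderStyle = RenderStyle(),
    distortion: DistortionModel = DistortionModel(),
    seed: int = 0,
) -> dict:
    """Render the lane grid into a simulated camera.

    Returns a dict with keys ``image`` (float grayscale, HxW in [0, 1]),
    ``lane_lines_true`` (analytic pre-distortion image lines) and
    ``v0_true`` (analytic lane vanishing point, pre-distortion).

    Raises
    ------
    ValueError
        The track is entirely out of frame for this camera.
    """
    proj = build_projection(camera)
    w, h = camera.image_size
    lines = analytic_lane_lines(proj, scene)
    visible = [ln for ln in lines if ln.support > 10.0]
    if len(visible) < 2:
        raise ValueError("track (at least two lane lines) not visible in frame")

    rng = np.random.default_rng(seed)
    yy = np.linspace(0.0, 1.0, h)[:, None]
    img = style.background_base + style.background_gradient * yy * np.ones((1, w))
    img = img + rng.normal(0.0, style.noise_sigma, size=(h, w))

    mask = np.zeros((h, w))
    for p0, p1 in lane_lines_3d(scene):
        seg = _clip_world_segment_to_front(p0, p1, proj)
        if seg is None:
            continue
        hom = np.hstack([np.vstack(seg), np.ones((2, 1))]) @ proj.P.T
        px = hom[:, :2] / hom[:, 2:3]
        clipped = _clip_to_box(px[0], px[1], w, h)
        if clipped is None:
            continue
        _draw_segment_aa(mask, clipped[0], clipped[1], style.line_width_px, 1.0)
    img = img * (1.0 - mask) + style.line_brightness * mask
    img = np.clip(img, 0.0, 1.0)
    img = _apply_radial_distortion(img, camera, distortion)
    return {"image": img, "lane_lines_true": tuple(visible), "v0_true": analytic_v0(proj)}


# ---------------------------------------------------------------------------
# Parametric runner


def _two_link_ik(hip: np.ndarray, ankle: np.ndarray, a: float, b: float) -> np.ndarray:
    """Knee position for a two-link leg, bending toward +x (running direction)."""
    d_vec = ankle - hip
    d = float(np.linalg.norm(d_vec))
    d = min(d, a + b - 1e-6)
    if d < 1e-9:
        return hip + np.array([a, 0.0, 0.0])
    e = d_vec / max(float(np.linalg.norm(d_vec)), 1e-12)
    # perpendicular within the sagittal (x-z) plane, pointing forward
    n = np.array([-e[2], 0.0, e[0]])
    nn = float(np.linalg.norm(n))
    n = n / nn if nn > 1e-9 else np.array([1.0, 0.0, 0.0])
    cos_a = (a * a + d * d - b * b) / (2.0 * a * d)
    cos_a = float(np.clip(cos_a, -1.0, 1.0))
    sin_a = math.sqrt(max(0.0, 1.0 - cos_a * cos_a))
    return hip + a * cos_a * e + a * sin_a * n


def _foot_x(s: float, gait: GaitConfig, phase0: float) -> tuple[float, float]:
    """World (x, z) of a foot at cycle coordinate s (= t*f + phase0)."""
    m = math.floor(s)
    u = s - m
    contact = gait.cycle_length * (m + gait.duty / 2.0 - phase0)
    if u < gait.duty:
        return contact, 0.0
    sw = (u - gait.duty) / (1.0 - gait.duty)
    # linear horizontal swing keeps the foot within duty/2 of a cycle of the
    # pelvis (inside leg reach); the abrupt stop at landing is heel-strike
    x = contact + sw * gait.cycle_length
    z = gait.lift_height * math.sin(math.pi * sw) ** 2
    return x, z


def generate_runner(
    gait: GaitConfig = GaitConfig(), n_frames: int = 50, seed: int = 0
) -> tuple[list[tuple[Skeleton3D, GroundPoint]], list[int]]:
    """Synthesize a 17-joint runner advancing along +x.

    Returns ``(frames, touchdown_frames)`` where each frame pairs the
    skeleton with its ground anchor (lowest ankle) and touch-down frames
    mark the first frame of each stance.  Deterministic: the gait is a
    pure function of its config; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    f_cyc = gait.speed / gait.cycle_length  # cycles per second
    frames: list[tuple[Skeleton3D, GroundPoint]] = []
    touchdowns: list[int] = []
    prev_m = {}
    y0 = gait.runner_y
    t0_off = 0.25  # start mid-swing so frame 0 is airborne-ish, not a contact edge
    for i in range(n_frames):
        t = i / gait.fps
        s_base = t * f_cyc + t0_off
        joints = np.zeros((17, 3))
        pelvis_x = gait.cycle_length * s_base
        pelvis_z = gait.pelvis_height + gait.bounce * math.cos(4.0 * math.pi * s_base)
        pelvis = np.array([pelvis_x, y0, pelvis_z])
        d_nav, d_chest, d_neck, d_head = gait.torso
        joints[JOINT_INDEX["pelvis"]] = pelvis
        joints[JOINT_INDEX["navel"]] = pelvis + [0, 0, d_nav]
        joints[JOINT_INDEX["chest"]] = pelvis + [0, 0, d_nav + d_chest]
        neck = pelvis + [0, 0, d_nav + d_chest + d_neck]
        joints[JOINT_INDEX["neck"]] = neck
        joints[JOINT_INDEX["head"]] = neck + [0, 0, d_head]

        for side, sgn, phase0 in (("left", 1.0, 0.0), ("right", -1.0, 0.5)):
            s = s_base + phase0
            hip = pelvis + np.array([0.0, sgn * gait.hip_half, 0.0])
            fx, fz = _foot_x(s, gait, phase0)
            ankle = np.array([fx, hip[1], fz])
            knee = _two_link_ik(hip, ankle, gait.thigh, gait.shank)
            joints[JOINT_INDEX[f"{side}_hip"]] = hip
            joints[JOINT_INDEX[f"{side}_knee"]] = knee
            joints[JOINT_INDEX[f"{side}_ankle"]] = ankle
            # touch-down bookkeeping: stance begins when the cycle index advances
            m = math.floor(s)
            if side in prev_m and m > prev_m[side]:
                touchdowns.append(i)
            prev_m[side] = m

            # arm opposite in phase to the same-side leg
            shoulder = neck + np.array([0.0, sgn * gait.shoulder_half, -0.02])
            theta = gait.arm_amp * math.sin(2.0 * math.pi * (s + 0.5))
            upper = np.array([math.sin(theta), 0.0, -math.cos(theta)])
            elbow = shoulder + gait.upper_arm * upper
            phi = theta + gait.elbow_bend
            fore = np.array([math.sin(phi), 0.0, -math.cos(phi)])
            wrist = elbow + gait.forearm * fore
            joints[JOINT_INDEX[f"{side}_shoulder"]] = shoulder
            joints[JOINT_INDEX[f"{side}_elbow"]] = elbow
            joints[JOINT_INDEX[f"{side}_wrist"]] = wrist

        skel = Skeleton3D(joints)
        contact = skel.joints[skel.ground_contact_index()]
        frames.append((skel, GroundPoint(xy=(contact[0], contact[1]))))
    touchdowns = sorted(set(touchdowns))
    return frames, touchdowns


def _yaw_about_anchor(skel: Skeleton3D, anchor_xy, yaw_deg: float) -> Skeleton3D:
    a = math.radians(yaw_deg)
    c, s = math.cos(a), math.sin(a)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    pivot = np.array([anchor_xy[0], anchor_xy[1], 0.0])
    return Skeleton3D((skel.joints - pivot) @ Rz.T + pivot)


def make_case(
    camera: CameraParams,
    scene: TrackScene = TrackScene(),
    gait: GaitConfig = GaitConfig(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    n_frames: int = 50,
    render_image: bool = True,
    style: RenderStyle = RenderStyle(),
    distortion: DistortionModel = DistortionModel(),
) -> SyntheticCase:
    """Assemble a full paired fixture.

    Clean pairs satisfy ``Skeleton2D == project(Skeleton3D)`` exactly;
    the noise config derives corrupted observations/predictions from them
    (seeded, deterministic).
    """
    from .pose_metrics import rotate_lower_leg  # local import avoids a cycle

    proj = build_projection(camera)
    rng = np.random.default_rng(seed)
    frames, touchdowns = generate_runner(gait, n_frames=n_frames, seed=seed)

    pairs = []
    anchors = []
    observed = []
    predicted = []
    n = len(frames)
    for i, (skel3d, anchor) in enumerate(frames):
        skel2d = Skeleton2D(_project_all(skel3d.joints, proj))
        pairs.append((skel3d, skel2d))
        anchors.append(anchor)

        obs = skel2d.joints.copy()
        if noise.jitter_2d_px > 0:
            obs = obs + rng.normal(0.0, noise.jitter_2d_px, size=obs.shape)
        observed.append(Skeleton2D(obs))

        pred = skel3d
        if noise.knee_bias_deg != 0.0:
            pred = rotate_lower_leg(pred, "left", noise.knee_bias_deg)
            pred = rotate_lower_leg(pred, "right", noise.knee_bias_deg)
        if noise.yaw_amp_deg != 0.0 and n > 1:
            yaw = noise.yaw_amp_deg * (2.0 * i / (n - 1) - 1.0)
            pred = _yaw_about_anchor(pred, anchor.xy, yaw)
        if noise.path_bend_m != 0.0 and n > 1:
            # lateral sagitta plus the tangent yaw a curved lift implies
            sag = noise.path_bend_m * math.sin(math.pi * i / (n - 1))
            dx_frame = gait.speed / gait.fps
            slope = (
                noise.path_bend_m
                * (math.pi / (n - 1))
                * math.cos(math.pi * i / (n - 1))
                / max(dx_frame, 1e-9)
            )
            pred = _yaw_about_anchor(pred, anchor.xy, math.degrees(math.atan(slope)))
            pred = pred.translated([0.0, sag, 0.0])
        predicted.append(pred)

    image = None
    lane_lines = analytic_lane_lines(proj, scene)
    if render_image:
        rendered = render_track(camera, scene, style, distortion, seed=seed)
        image = rendered["image"]
        lane_lines = rendered["lane_lines_true"]
    return SyntheticCase(
        camera_truth=camera,
        image=image,
        lane_lines_true=tuple(lane_lines),
        v0_true=analytic_v0(proj),
        skeletons=tuple(pairs),
        anchors=tuple(anchors),
        touchdown_frames=tuple(touchdowns),
        observed_2d=tuple(observed),
        predicted_3d=tuple(predicted),
        seed=seed,
    )


def _project_all(points: np.ndarray, proj: ProjectionMatrix) -> np.ndarray:
    hom = np.hstack([points, np.ones((points.shape[0], 1))]) @ proj.P.T
    w = hom[:, 2]
    if np.any(w <= 0):
        raise ValueError("runner behind the camera; move the camera or the runner")
    return hom[:, :2] / w[:, None]
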