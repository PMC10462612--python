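"""Evaluation of monocular 3D pose estimates against recovered scene geometry.

Given a reference 2D skeleton, a predicted 3D skeleton and the true
camera, the audit places the 3D skeleton on the ground where the
reference's supporting foot ray-traces, matches its projected height,
projects it, aligns the projection to the reference by scale +
translation, and measures four errors:

* reprojection error in pixels (mean per-joint offset over 17 joints);
* the same scaled to millimetres by the athlete's real-world vs pixel
  height (an image-scale approximation, not a true 3D distance);
* 2D knee-angle error in degrees;
* an approximate 3D knee-angle error, obtained by perturbing the
  predicted knee in 3D and measuring how strongly that moves the 2D
  angle: a camera in the runner's sagittal plane sees 2D angle changes
  one-for-one, while a near-frontal camera compresses them, so the 2D
  error is divided by the measured sensitivity.

Two correction strategies inject scene knowledge that the pose estimator
does not have: "movement" straightens the predicted ground path onto a
line (home-stretch runners move straight), and "rotation" re-yaws every
skeleton to face the finish line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .camera_model import (
    CameraParams,
    GroundPoint,
    NoIntersectionError,
    ProjectionMatrix,
    build_projection,
    ray_trace_to_ground,
)
from .scene_model import (
    JOINT_INDEX,
    Skeleton2D,
    Skeleton3D,
    TrackScene,
    place_skeleton,
    project_skeleton,
    scale_skeleton,
)

__all__ = [
    "AlignmentTransform",
    "ErrorReport",
    "MetricsConfig",
    "align_2d",
    "apply_alignment",
    "reprojection_error",
    "knee_angle_2d",
    "knee_angle_3d",
    "rotate_lower_leg",
    "knee_sensitivity",
    "approx_3d_knee_error",
    "detect_touchdown_frames",
    "straighten_path",
    "facing_direction",
    "rotate_to_facing",
    "evaluate",
]

SIDES = ("left", "right")


@dataclass(frozen=True)
class AlignmentTransform:
    """2D similarity without rotation: x -> scale * x + translation."""

    scale: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"alignment scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class MetricsConfig:
    athlete_height_mm: float = 1800.0
    perturb_delta_deg: float = 1.0       # knee perturbation for the 3D approximation
    sensitivity_floor: float = 0.05      # below this the 3D approximation is capped
    touchdown_window: int = 5            # frames, local-extremum window
    touchdown_disp_frac: float = 0.012   # max absolute ankle motion per frame,
                                         # as a fraction of skeleton height (a
                                         # planted foot is world-stationary)
    touchdown_depth_frac: float = 0.07   # ankle counts as "lowest" within this
                                         # fraction of skeleton height of the
                                         # reference maximum (the image-lowest
                                         # point can precede contact under
                                         # perspective)
    touchdown_depth_window: int = 15     # frames for the lowest-point reference;
                                         # spans a step so the swing apex cannot
                                         # pass as "lowest"

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsConfig":
        return replace(cls(), **d)


@dataclass(frozen=True)
class ErrorReport:
    """Aggregate audit metrics: mean (sd) per metric plus per-frame arrays."""

    reproj_px: float
    reproj_px_sd: float
    reproj_mm: float
    reproj_mm_sd: float
    knee2d_deg: float
    knee2d_sd: float
    knee3d_approx_deg: float
    knee3d_sd: float
    per_frame: dict
    n_frames: int
    n_skipped: int = 0

    def as_row(self, method: str = "") -> dict:
        return {
            "method": method,
            "reproj_px_mean": self.reproj_px,
            "reproj_px_sd": self.reproj_px_sd,
            "reproj_mm_mean": self.reproj_mm,
            "reproj_mm_sd": self.reproj_mm_sd,
            "knee2d_mean": self.knee2d_deg,
            "knee2d_sd": self.knee2d_sd,
            "knee3d_mean": self.knee3d_approx_deg,
            "knee3d_sd": self.knee3d_sd,
        }


# ---------------------------------------------------------------------------
# Alignment and reprojection


def align_2d(projected: Skeleton2D, reference: Skeleton2D) -> AlignmentTransform:
    """Least-squares scale + translation mapping ``projected`` onto ``reference``.

    Closed form: with centred coordinates p', r', the optimal scale is
    <p', r'> / <p', p'> and the translation re-centres the means.  No
    rotation component.

    Raises
    ------
    ValueError
        Degenerate input (all joints of either skeleton coincident).
    """
    p = projected.joints
    r = reference.joints
    pc = p - p.mean(axis=0)
    rc = r - r.mean(axis=0)
    denom = float((pc * pc).sum())
    if denom < 1e-12 or float((rc * rc).sum()) < 1e-12:
        raise ValueError("degenerate skeleton: all joints coincident")
    s = float((pc * rc).sum()) / denom
    if s <= 0:
        raise ValueError("alignment collapsed to non-positive scale")
    t = r.mean(axis=0) - s * p.mean(axis=0)
    return AlignmentTransform(scale=s, translation=(float(t[0]), float(t[1])))


def apply_alignment(skel: Skeleton2D, tf: AlignmentTransform) -> Skeleton2D:
    return Skeleton2D(skel.joints * tf.scale + np.asarray(tf.translation))


def reprojection_error(
    skel3d: Skeleton3D,
    proj: ProjectionMatrix,
    reference: Skeleton2D,
    athlete_height_mm: float = 1800.0,
    *,
    align: bool = True,
) -> tuple[float, float]:
    """Mean per-joint pixel offset and its height-scaled mm approximation.

    The projection is first aligned (scale + translation) to the
    reference; the mm figure multiplies the pixel error by
    ``athlete_height_mm / reference pixel height`` — an image-scale
    conversion, not a true 3D joint distance.

    Raises
    ------
    ValueError
        The reference skeleton has zero pixel height.
    """
    proj2d = project_skeleton(skel3d, proj)
    if align:
        proj2d = apply_alignment(proj2d, align_2d(proj2d, reference))
    offsets = np.linalg.norm(proj2d.joints - reference.joints, axis=1)
    px = float(offsets.mean())
    ref_h = reference.height
    if ref_h <= 0:
        raise ValueError("reference skeleton has zero pixel height")
    return px, px * athlete_height_mm / ref_h


# ---------------------------------------------------------------------------
# Knee angles


def _interior_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("coincident joints: knee angle undefined")
    c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(c))


def knee_angle_2d(skel: Skeleton2D, side: str) -> float:
    """Interior angle at the knee between knee->hip and knee->ankle, degrees."""
    hip = skel.joint(f"{side}_hip")
    knee = skel.joint(f"{side}_knee")
    ankle = skel.joint(f"{side}_ankle")
    return _interior_angle(hip - knee, ankle - knee)


def knee_angle_3d(skel: Skeleton3D, side: str) -> float:
    hip = skel.joint(f"{side}_hip")
    knee = skel.joint(f"{side}_knee")
    ankle = skel.joint(f"{side}_ankle")
    return _interior_angle(hip - knee, ankle - knee)


def _flexion_axis(skel: Skeleton3D, side: str) -> np.ndarray:
    """Normal of the hip-knee-ankle plane (the knee's flexion axis)."""
    hip = skel.joint(f"{side}_hip")
    knee = skel.joint(f"{side}_knee")
    ankle = skel.joint(f"{side}_ankle")
    axis = np.cross(hip - knee, ankle - knee)
    n = np.linalg.norm(axis)
    if n < 1e-9:  # straight leg: fall back to the lateral axis
        axis = np.array([0.0, 1.0, 0.0])
        n = 1.0
    return axis / n


def rotate_lower_leg(skel: Skeleton3D, side: str, angle_deg: float) -> Skeleton3D:
    """Rotate the ankle about the knee by ``angle_deg`` about the flexion axis."""
    axis = _flexion_axis(skel, side)
    knee = skel.joint(f"{side}_knee")
    ankle = skel.joint(f"{side}_ankle")
    a = math.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    R = np.eye(3) + math.sin(a) * K + (1.0 - math.cos(a)) * (K @ K)
    joints = skel.joints.copy()
    joints[JOINT_INDEX[f"{side}_ankle"]] = knee + R @ (ankle - knee)
    return Skeleton3D(joints)


def knee_sensitivity(
    skel3d: Skeleton3D,
    proj: ProjectionMatrix,
    side: str,
    delta: float = 1.0,
) -> float:
    """d(2D knee angle)/d(3D knee angle) at the current pose, central-differenced.

    Close to 1 for a sagittal (side-on) camera, and smaller the more
    frontal the view: the same 3D flexion then moves the 2D angle less.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    base2d = knee_angle_2d(project_skeleton(skel3d, proj), side)
    base3d = knee_angle_3d(skel3d, side)
    num = 0.0
    den = 0.0
    for sgn in (+1.0, -1.0):
        pert = rotate_lower_leg(skel3d, side, sgn * delta)
        num += abs(knee_angle_2d(project_skeleton(pert, proj), side) - base2d)
        # the realised 3D change, not the nominal delta: near a straight
        # leg the interior angle folds at 180 deg
        den += abs(knee_angle_3d(pert, side) - base3d)
    if den < 1e-9:
        return 0.0
    return num / den


def approx_3d_knee_error(
    skel3d: Skeleton3D,
    proj: ProjectionMatrix,
    knee2d_error: float,
    side: str,
    delta: float = 1.0,
    *,
    sensitivity_floor: float = 0.05,
) -> tuple[float, bool]:
    """Scale a measured 2D knee error to an approximate 3D error.

    Simulates +-delta of knee flexion in the predicted 3D skeleton,
    records the effect on the projected 2D knee angle, and divides the
    measured 2D error by that sensitivity.  Returns ``(error_deg,
    capped)`` where ``capped`` flags near-degenerate viewing (sensitivity
    below the floor; the estimate is then computed at the floor).
    """
    s = knee_sensitivity(skel3d, proj, side, delta)
    if s < sensitivity_floor:
        return knee2d_error / sensitivity_floor, True
    return knee2d_error / s, False


# ---------------------------------------------------------------------------
# Touch-down detection


def detect_touchdown_frames(
    seq: list[Skeleton2D], config: MetricsConfig = MetricsConfig()
) -> list[int]:
    """Frames where an ankle is lowest in the image and nearly still.

    A frame qualifies for an ankle when its image y is a local maximum
    over the configured window (lowest point; image y grows downward) and
    the pelvis-relative frame-to-frame y-motion is below
    ``touchdown_disp_frac`` of the skeleton's pixel height.  Consecutive
    qualifying frames are one stance: its first frame is reported as the
    touch-down.  If the whole sequence qualifies (stationary skeleton),
    the run midpoint is reported instead.

    Raises
    ------
    ValueError
        Sequence shorter than 5 frames.
    """
    n = len(seq)
    if n < 5:
        raise ValueError("need at least 5 frames to detect touch-downs")
    half = max(1, config.touchdown_window // 2)
    heights = np.array([max(s.height, 1e-9) for s in seq])
    qualifying = np.zeros(n, dtype=bool)
    # the pelvis reference cancels camera pan but carries the vertical gait
    # bounce, and the raw pixel height breathes with the pose; smooth both
    # over roughly a step so only camera motion and scale survive
    w = min(max(3, config.touchdown_depth_window), n)
    kernel = np.ones(w) / w

    def _smooth(x):
        padded = np.concatenate([np.full(w // 2, x[0]), x, np.full(w // 2, x[-1])])
        return np.convolve(padded, kernel, mode="valid")[:n]

    pelvis_ref = _smooth(np.array([s.joint("pelvis")[1] for s in seq]))
    heights = _smooth(heights)
    for side in SIDES:
        pts = np.array([s.joint(f"{side}_ankle") for s in seq])
        # height-normalised drop below the (smoothed) pelvis: scale-free, so
        # camera zoom/recession does not tilt the stance plateau
        rel = (pts[:, 1] - pelvis_ref) / heights
        # a planted foot is world-stationary: its absolute image displacement
        # vanishes through the stance.  Forward difference so the first
        # stance frame (heel-strike) already qualifies.
        disp = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        vel = np.concatenate([disp, [0.0]]) / heights
        dhalf = max(half, config.touchdown_depth_window // 2)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            if hi - lo < config.touchdown_window:  # truncated boundary window
                continue
            lo2, hi2 = max(0, i - dhalf), min(n, i + dhalf + 1)
            near_lowest = rel[i] >= rel[lo2:hi2].max() - config.touchdown_depth_frac
            if near_lowest and vel[i] <= config.touchdown_disp_frac:
                qualifying[i] = True
    idx = np.flatnonzero(qualifying)
    if len(idx) == 0:
        return []
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    if len(runs) == 1 and len(runs[0]) >= n - 2 * half:  # stationary degenerate
        return [runs[0][len(runs[0]) // 2]]
    return [r[0] for r in runs]


# ---------------------------------------------------------------------------
# Correction strategies


def straighten_path(
    seq3d: list[Skeleton3D], anchors: list[GroundPoint]
) -> tuple[list[Skeleton3D], list[GroundPoint]]:
    """Project ground anchors onto their total-least-squares line.

    Home-stretch athletes run straight; a curved predicted path is a
    lifting artefact.  Each skeleton is rigidly translated so its anchor
    lands on its orthogonal projection onto the TLS line through all
    anchors.  Coincident anchors leave the sequence unchanged (warning).
    """
    if len(seq3d) < 2 or len(seq3d) != len(anchors):
        raise ValueError("need >= 2 frames with matching anchors")
    pts = np.array([a.xy for a in anchors])
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    if float((rel**2).sum()) < 1e-18:
        warnings.warn("all anchors coincident; path left unchanged", stacklevel=2)
        return list(seq3d), list(anchors)
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    d = vt[0]
    proj_pts = centroid + (rel @ d)[:, None] * d
    out_s, out_a = [], []
    for skel, p_old, p_new in zip(seq3d, pts, proj_pts):
        shift = np.array([p_new[0] - p_old[0], p_new[1] - p_old[1], 0.0])
        out_s.append(skel.translated(shift))
        out_a.append(GroundPoint(xy=(p_new[0], p_new[1])))
    return out_s, out_a


def facing_direction(skel: Skeleton3D) -> np.ndarray:
    """Horizontal unit vector the skeleton faces.

    Perpendicular of the left-hip -> right-hip vector, on the
    chest-forward side: with x forward, z up, the left hip sits at larger
    y, so facing = normalize((-h_y, h_x)) for h = right_hip - left_hip.
    """
    h = skel.joint("right_hip") - skel.joint("left_hip")
    f = np.array([-h[1], h[0]])
    n = np.linalg.norm(f)
    if n < 1e-9:
        raise ValueError("degenerate hips: facing undefined")
    return f / n


def rotate_to_facing(skel: Skeleton3D, facing) -> Skeleton3D:
    """Yaw the skeleton about the vertical through its ground anchor so it
    faces the given horizontal unit direction (e.g. (1, 0): the finish)."""
    f_cur = facing_direction(skel)
    f_tgt = np.asarray(facing, dtype=float)
    n = np.linalg.norm(f_tgt)
    if n == 0:
        raise ValueError("target facing must be nonzero")
    f_tgt = f_tgt / n
    ang = math.atan2(f_tgt[1], f_tgt[0]) - math.atan2(f_cur[1], f_cur[0])
    c, s = math.cos(ang), math.sin(ang)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    contact = skel.joints[skel.ground_contact_index()]
    pivot = np.array([contact[0], contact[1], 0.0])
    return Skeleton3D((skel.joints - pivot) @ Rz.T + pivot)


# ---------------------------------------------------------------------------
# Full audit pipeline


def _audit_frame(
    ref2d: Skeleton2D,
    skel3d: Skeleton3D,
    proj: ProjectionMatrix,
    config: MetricsConfig,
) -> dict:
    reproj_px, reproj_mm = reprojection_error(
        skel3d, proj, ref2d, config.athlete_height_mm
    )
    proj2d = project_skeleton(skel3d, proj)
    proj2d = apply_alignment(proj2d, align_2d(proj2d, ref2d))
    knee_errs, knee3d_errs = [], []
    for side in SIDES:
        e2d = abs(knee_angle_2d(proj2d, side) - knee_angle_2d(ref2d, side))
        knee_errs.append(e2d)
        e3d, _ = approx_3d_knee_error(
            skel3d, proj, e2d, side, config.perturb_delta_deg,
            sensitivity_floor=config.sensitivity_floor,
        )
        knee3d_errs.append(e3d)
    return {
        "reproj_px": reproj_px,
        "reproj_mm": reproj_mm,
        "knee2d_deg": float(np.mean(knee_errs)),
        "knee3d_deg": float(np.mean(knee3d_errs)),
    }


def _place_and_scale(
    ref2d: Skeleton2D, skel3d: Skeleton3D, proj: ProjectionMatrix
) -> tuple[Skeleton3D, GroundPoint]:
    # anchor on the predicted supporting foot (lowest 3D ankle): under
    # perspective the image-lowest ankle can be the airborne nearer foot
    anchor_px = ref2d.joints[skel3d.ground_contact_index()]
    anchor = ray_trace_to_ground(anchor_px, proj)
    placed = place_skeleton(skel3d, anchor)
    scaled = scale_skeleton(placed, ref2d.height, proj, tol_px=1e-3)
    return scaled, anchor


def evaluate(
    frames: list[tuple[Skeleton2D, Skeleton3D, CameraParams]],
    scene: TrackScene = TrackScene(),
    config: MetricsConfig = MetricsConfig(),
    strategy: str = "base",
) -> ErrorReport:
    """Run the full per-frame audit and aggregate mean (sd) per metric.

    Per frame: ray-trace the reference foot to the ground, place and scale
    the predicted 3D skeleton there, optionally apply a correction
    strategy ("base", "movement" = straighten the path, "rotation" = face
    the finish line), project, align, and measure all four metrics.
    Frames whose placement fails are skipped and counted, not fatal.
    """
    if strategy not in ("base", "movement", "rotation"):
        raise ValueError(f"unknown strategy {strategy!r}")
    placed = []
    n_skipped = 0
    for ref2d, skel3d, cam in frames:
        proj = build_projection(cam)
        pred_anchor = skel3d.joints[skel3d.ground_contact_index()][:2]
        try:
            scaled, anchor = _place_and_scale(ref2d, skel3d, proj)
        except (NoIntersectionError, ValueError):
            n_skipped += 1
            continue
        placed.append((ref2d, scaled, proj, anchor, pred_anchor))
    if not placed:
        raise ValueError("no frame could be placed in the scene")

    if strategy == "movement" and len(placed) >= 2:
        # straighten the *predicted* path: a curved lifted trajectory yaws
        # the skeletons along its tangent, so mapping each local tangent
        # onto the fitted line both undoes that yaw and (with the anchor
        # translation of straighten_path) straightens the positions
        pred_pts = np.array([p[4] for p in placed])
        rel = pred_pts - pred_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        line_dir = vt[0] if vt[0, 0] >= 0 else -vt[0]
        corrected = []
        m = len(placed)
        for i, (ref, s, proj, a, _) in enumerate(placed):
            lo, hi = max(0, i - 1), min(m - 1, i + 1)
            tangent = pred_pts[hi] - pred_pts[lo]
            if np.linalg.norm(tangent) < 1e-12:
                corrected.append((ref, s, proj, a))
                continue
            yaw = math.atan2(line_dir[1], line_dir[0]) - math.atan2(tangent[1], tangent[0])
            c, sn = math.cos(yaw), math.sin(yaw)
            Rz = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
            pivot = np.array([a.xy[0], a.xy[1], 0.0])
            s_rot = Skeleton3D((s.joints - pivot) @ Rz.T + pivot)
            corrected.append((ref, s_rot, proj, a))
        skels, anchors = straighten_path(
            [c[1] for c in corrected], [c[3] for c in corrected]
        )
        placed = [
            (ref, s, proj, a)
            for (ref, _, proj, _), s, a in zip(corrected, skels, anchors)
        ]
    elif strategy == "rotation":
        placed = [
            (ref, rotate_to_facing(s, (1.0, 0.0)), proj, a)
            for ref, s, proj, a, _ in placed
        ]
    else:
        placed = [(ref, s, proj, a) for ref, s, proj, a, _ in placed]

    rows = [_audit_frame(ref, s, proj, config) for ref, s, proj, _ in placed]
    per_frame = {k: np.array([r[k] for r in rows]) for k in rows[0]}

    def ms(key):
        v = per_frame[key]
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    rpx, rpx_sd = ms("reproj_px")
    rmm, rmm_sd = ms("reproj_mm")
    k2, k2_sd = ms("knee2d_deg")
    k3, k3_sd = ms("knee3d_deg")
    return ErrorReport(
        reproj_px=rpx, reproj_px_sd=rpx_sd,
        reproj_mm=rmm, reproj_mm_sd=rmm_sd,
        knee2d_deg=k2, knee2d_sd=k2_sd,
        knee3d_approx_deg=k3, knee3d_sd=k3_sd,
        per_frame=per_frame, n_frames=len(placed), n_skipped=n_skipped,
    )
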