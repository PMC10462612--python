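"""Standardised track geometry and 17-joint skeleton containers.

The home stretch is modelled as a family of parallel lane lines on the
ground plane, 1.22 m apart (IAAF/World Athletics lane width).  Skeletons
use the 17 joints common to HPE benchmarks (human3.6m convention), in a
fixed order so that JSON I/O is deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .camera_model import GroundPoint, ProjectionMatrix, project_points

__all__ = [
    "JOINT_NAMES",
    "TrackScene",
    "Skeleton3D",
    "Skeleton2D",
    "lane_lines_3d",
    "place_skeleton",
    "scale_skeleton",
    "skeleton_to_json",
    "skeleton_from_json",
]

#: Fixed joint order (head-to-toe reading order of the 17 human3.6m joints).
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "chest",
    "navel",
    "pelvis",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

JOINT_INDEX = {name: i for i, name in enumerate(JOINT_NAMES)}


@dataclass(frozen=True)
class TrackScene:
    """Parallel lane lines on the ground plane of the home stretch.

    ``n_lanes`` counts lane *lines* (9 lines bound 8 running lanes);
    ``lane_extent`` is how far along x the lines are rendered/considered.
    """

    lane_width: float = 1.22
    n_lanes: int = 9
    lane_extent: tuple[float, float] = (-60.0, 120.0)

    def __post_init__(self) -> None:
        if self.lane_width <= 0:
            raise ValueError(f"lane_width must be positive, got {self.lane_width}")
        if self.n_lanes < 2:
            raise ValueError(f"need at least 2 lane lines, got {self.n_lanes}")


def _check_joints(joints: np.ndarray, dim: int) -> np.ndarray:
    joints = np.asarray(joints, dtype=float)
    if joints.shape != (17, dim):
        raise ValueError(f"expected (17, {dim}) joints, got {joints.shape}")
    if not np.all(np.isfinite(joints)):
        raise ValueError("joint coordinates must be finite")
    return joints


@dataclass(frozen=True)
class Skeleton3D:
    """17 named joints in metric world coordinates."""

    joints: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "joints", _check_joints(self.joints, 3))

    def joint(self, name: str) -> np.ndarray:
        return self.joints[JOINT_INDEX[name]]

    @property
    def height(self) -> float:
        """Vertical extent: max joint z minus min joint z."""
        return float(self.joints[:, 2].max() - self.joints[:, 2].min())

    def ground_contact_index(self) -> int:
        """Index of the designated ground-contact joint: the lowest ankle."""
        la, ra = JOINT_INDEX["left_ankle"], JOINT_INDEX["right_ankle"]
        return la if self.joints[la, 2] <= self.joints[ra, 2] else ra

    def translated(self, offset) -> "Skeleton3D":
        return Skeleton3D(self.joints + np.asarray(offset, dtype=float))


@dataclass(frozen=True)
class Skeleton2D:
    """17 named joints in pixel coordinates (image y down)."""

    joints: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "joints", _check_joints(self.joints, 2))

    def joint(self, name: str) -> np.ndarray:
        return self.joints[JOINT_INDEX[name]]

    @property
    def height(self) -> float:
        """Vertical pixel extent: max image y minus min image y."""
        return float(self.joints[:, 1].max() - self.joints[:, 1].min())

    def lowest_ankle_index(self) -> int:
        """Index of the ankle lowest in the image (largest y)."""
        la, ra = JOINT_INDEX["left_ankle"], JOINT_INDEX["right_ankle"]
        return la if self.joints[la, 1] >= self.joints[ra, 1] else ra


def lane_lines_3d(scene: TrackScene) -> list[tuple[np.ndarray, np.ndarray]]:
    """Endpoints of the lane-line segments: n_lanes parallel segments along x.

    Line k runs from (x0, k*lane_width, 0) to (x1, k*lane_width, 0).
    """
    x0, x1 = scene.lane_extent
    return [
        (
            np.array([x0, k * scene.lane_width, 0.0]),
            np.array([x1, k * scene.lane_width, 0.0]),
        )
        for k in range(scene.n_lanes)
    ]


def place_skeleton(skel: Skeleton3D, anchor: GroundPoint) -> Skeleton3D:
    """Translate a skeleton so its ground-contact joint (lowest ankle) sits
    at (anchor.x, anchor.y, 0).  Internal joint offsets are unchanged."""
    contact = skel.joints[skel.ground_contact_index()]
    target = np.array([anchor.xy[0], anchor.xy[1], 0.0])
    return skel.translated(target - contact)


def project_skeleton(skel: Skeleton3D, proj: ProjectionMatrix) -> Skeleton2D:
    """Project all 17 joints through a pinhole camera."""
    return Skeleton2D(project_points(skel.joints, proj))


def scale_skeleton(
    skel: Skeleton3D,
    target_height_px: float,
    proj: ProjectionMatrix,
    *,
    tol_px: float = 0.5,
    max_iter: int = 80,
) -> Skeleton3D:
    """Scale a skeleton about its ground-contact joint until its projected
    vertical extent matches ``target_height_px``.

    Solved by bisection on the scale factor; projected height is monotone in
    scale for any camera in front of which the skeleton stays.

    Raises
    ------
    ValueError
        Non-positive target, or no convergence after ``max_iter`` iterations.
    """
    if target_height_px <= 0:
        raise ValueError(f"target height must be positive, got {target_height_px}")
    pivot = skel.joints[skel.ground_contact_index()].copy()
    offsets = skel.joints - pivot

    def height_at(s: float) -> float:
        pts = pivot + s * offsets
        return float(np.ptp(project_points(pts, proj)[:, 1]))

    lo, hi = 1.0, 1.0
    h0 = height_at(1.0)
    if h0 <= 0:
        raise ValueError("skeleton has zero projected height")
    # bracket the target
    for _ in range(60):
        if height_at(hi) >= target_height_px:
            break
        hi *= 2.0
    for _ in range(60):
        if height_at(lo) <= target_height_px:
            break
        lo /= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        h = height_at(mid)
        if abs(h - target_height_px) <= tol_px:
            return Skeleton3D(pivot + mid * offsets)
        if h < target_height_px:
            lo = mid
        else:
            hi = mid
    raise ValueError("scale_skeleton did not converge")


# ---------------------------------------------------------------------------
# JSON I/O: {"joints": {"head": [x, y, (z)], ...}, "space": "pixel"|"metric"}


def skeleton_to_json(skel: Skeleton3D | Skeleton2D) -> str:
    space = "metric" if isinstance(skel, Skeleton3D) else "pixel"
    joints = {name: [float(v) for v in skel.joints[i]] for i, name in enumerate(JOINT_NAMES)}
    return json.dumps({"joints": joints, "space": space})


def skeleton_from_json(text: str) -> Skeleton3D | Skeleton2D:
    d = json.loads(text)
    space = d.get("space")
    joints = np.array([d["joints"][name] for name in JOINT_NAMES], dtype=float)
    if space == "metric":
        return Skeleton3D(joints)
    if space == "pixel":
        return Skeleton2D(joints)
    raise ValueError(f"unknown skeleton space {space!r}")
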