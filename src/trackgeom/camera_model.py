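"""Pinhole camera model for track-side broadcast geometry.

World frame (right-handed): ``x`` is the running direction down the home
stretch, ``y`` is lateral across the lanes, ``z`` is up.  Lane line ``k``
is the set ``{y = k * lane_width, z = 0}``.

Image frame: origin at the top-left pixel corner, ``x`` right, ``y`` down.
The virtual camera has square pixels, zero skew and its principal point at
the exact centre of the frame, so the single free intrinsic parameter is
the horizontal field of view.

A world point ``X`` projects through ``P = K [R | t]`` (with ``t = -R C``
for camera centre ``C``) as ``(u, v, w) = P (X, Y, Z, 1)^T`` and pixel
coordinates ``(u/w, v/w)``; ``w > 0`` means the point is in front of the
camera.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CameraParams",
    "ProjectionMatrix",
    "GroundPoint",
    "AtInfinity",
    "BehindCameraError",
    "NoIntersectionError",
    "InvalidCameraError",
    "build_projection",
    "project_points",
    "vanishing_point_of_direction",
    "ray_trace_to_ground",
    "load_camera",
    "save_camera",
]


class InvalidCameraError(ValueError):
    """Camera parameters outside their valid domain."""


class BehindCameraError(ValueError):
    """A point to be projected lies behind the camera (w < 0)."""


class NoIntersectionError(ValueError):
    """A back-projected ray does not meet the ground plane in front of the camera."""


class AtInfinity:
    """Marker for an image point at infinity (direction parallel to the image plane)."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "AtInfinity()"


@dataclass(frozen=True)
class CameraParams:
    """Extrinsic + intrinsic parameters of a pan/tilt/zoom pinhole camera.

    Parameters
    ----------
    azimuth : float
        Pan about the world vertical, degrees.  Zero points down the lanes
        (+x); positive pans toward +y.  May be negative (mirrored stand side).
    elevation : float
        Tilt below the horizontal, degrees, in [0, 90).
    roll : float
        Rotation about the optical axis, degrees.  Broadcast horizon is
        horizontal, so roll is 0 throughout the calibration path.
    fov : float
        Horizontal field of view, degrees, in (0, 180).
    position : array-like of 3 floats
        Camera centre in the world frame, metres.
    image_size : (int, int)
        (width, height) in pixels.
    """

    azimuth: float
    elevation: float
    roll: float
    fov: float
    position: tuple[float, float, float]
    image_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        if not (0.0 < self.fov < 180.0):
            raise InvalidCameraError(f"fov must lie in (0, 180) deg, got {self.fov}")
        if not (0.0 <= self.elevation < 90.0):
            raise InvalidCameraError(
                f"elevation must lie in [0, 90) deg, got {self.elevation}"
            )
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise InvalidCameraError(f"image_size must be positive, got {self.image_size}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))

    @property
    def focal_px(self) -> float:
        """Focal length in pixels implied by the fov and image width."""
        return focal_from_fov(self.fov, self.image_size[0])

    @property
    def principal_point(self) -> np.ndarray:
        w, h = self.image_size
        return np.array([w / 2.0, h / 2.0])


@dataclass(frozen=True)
class ProjectionMatrix:
    """Composite pinhole projection ``P = K [R | t]`` with its factors."""

    K: np.ndarray
    R: np.ndarray
    t: np.ndarray
    P: np.ndarray = field(init=False)
    image_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "P", K @ np.hstack([R, t[:, None]]))

    @property
    def camera_center(self) -> np.ndarray:
        """Camera centre C in world coordinates (t = -R C)."""
        return -self.R.T @ self.t

    @property
    def principal_point(self) -> np.ndarray:
        w, h = self.image_size
        return np.array([w / 2.0, h / 2.0])


@dataclass(frozen=True)
class GroundPoint:
    """A point on the ground plane z = 0, metres."""

    xy: tuple[float, float]

    def __post_init__(self) -> None:
        xy = (float(self.xy[0]), float(self.xy[1]))
        if not all(math.isfinite(v) for v in xy):
            raise ValueError(f"ground point must be finite, got {xy}")
        object.__setattr__(self, "xy", xy)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.xy[0], self.xy[1], 0.0])


def focal_from_fov(fov_deg: float, image_width: int) -> float:
    """Pixel focal length from horizontal field of view: f = (W/2)/tan(fov/2)."""
    if not (0.0 < fov_deg < 180.0):
        raise InvalidCameraError(f"fov must lie in (0, 180) deg, got {fov_deg}")
    return (image_width / 2.0) / math.tan(math.radians(fov_deg) / 2.0)


def fov_from_focal(focal_px: float, image_width: int) -> float:
    """Inverse of :func:`focal_from_fov`."""
    return math.degrees(2.0 * math.atan((image_width / 2.0) / focal_px))


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


# Frame alignment at azimuth = elevation = roll = 0: optical axis along the
# lane direction (+x world), image-right along -y world, image-down along -z
# world.  Rows are the camera axes expressed in world coordinates.
_BASE = np.array(
    [
        [0.0, -1.0, 0.0],
        [0.0, 0.0, -1.0],
        [1.0, 0.0, 0.0],
    ]
)


def rotation_world_to_camera(azimuth_deg: float, elevation_deg: float, roll_deg: float) -> np.ndarray:
    """World->camera rotation as roll(optical axis) . tilt(camera x) . pan(world z).

    Positive azimuth pans the view from +x toward +y; positive elevation tilts
    the camera down below the horizontal; with roll = 0 the image of the
    ground-plane horizon is exactly horizontal.
    """
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    ro = math.radians(roll_deg)
    return _rot_z(ro) @ _rot_x(el) @ _BASE @ _rot_z(-az)


def build_projection(params: CameraParams) -> ProjectionMatrix:
    """Compose K, R, t and P = K [R | t] from camera parameters.

    Raises
    ------
    InvalidCameraError
        If fov is degenerate (<= 0 or >= 180 degrees).
    """
    f = params.focal_px
    w, h = params.image_size
    K = np.array([[f, 0.0, w / 2.0], [0.0, f, h / 2.0], [0.0, 0.0, 1.0]])
    R = rotation_world_to_camera(params.azimuth, params.elevation, params.roll)
    C = np.asarray(params.position, dtype=float)
    t = -R @ C
    return ProjectionMatrix(K=K, R=R, t=t, image_size=params.image_size)


def project_points(points, proj: ProjectionMatrix, *, allow_behind: bool = False) -> np.ndarray:
    """Project world points (metres) to pixel coordinates.

    Parameters
    ----------
    points : (n, 3) array-like
    proj : ProjectionMatrix
    allow_behind : bool
        If False (default), raise :class:`BehindCameraError` when any point
        has w < 0 (behind the principal plane).

    Raises
    ------
    BehindCameraError
        A point projects with w < 0 and ``allow_behind`` is False.
    ValueError
        A point lies exactly on the principal plane (w = 0).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
    uvw = hom @ proj.P.T
    w = uvw[:, 2]
    if np.any(w == 0.0):
        raise ValueError("point on the principal plane projects to infinity (w = 0)")
    if not allow_behind and np.any(w < 0.0):
        raise BehindCameraError("point(s) behind the camera (w < 0)")
    out = uvw[:, :2] / w[:, None]
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def vanishing_point_of_direction(direction, proj: ProjectionMatrix, *, parallel_tol: float = 1e-12):
    """Image of a 3D direction (its point at infinity): dehomogenised K R d.

    Independent of the camera position by construction.  Returns an
    :class:`AtInfinity` marker when the direction is parallel to the image
    plane (the vanishing point lies at infinity), never an exception.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be nonzero")
    h = proj.K @ (proj.R @ (d / n))
    if abs(h[2]) < parallel_tol * max(1.0, np.abs(h[:2]).max()):
        return AtInfinity()
    return h[:2] / h[2]


def ray_trace_to_ground(pixel, proj: ProjectionMatrix) -> GroundPoint:
    """Back-project a pixel and intersect the ray with the ground plane z = 0.

    Raises
    ------
    NoIntersectionError
        The ray is parallel to the ground or meets it behind the camera
        (pixel on or above the horizon line).
    """
    p = np.asarray(pixel, dtype=float)
    d_cam = np.linalg.solve(proj.K, np.array([p[0], p[1], 1.0]))
    d_world = proj.R.T @ d_cam
    C = proj.camera_center
    if d_world[2] == 0.0:
        raise NoIntersectionError("ray parallel to the ground plane (pixel on the horizon)")
    lam = -C[2] / d_world[2]
    if lam <= 0.0:
        raise NoIntersectionError("ray meets the ground plane behind the camera")
    X = C + lam * d_world
    return GroundPoint(xy=(X[0], X[1]))


# ---------------------------------------------------------------------------
# Camera parameter file I/O (YAML or JSON)

_CAM_KEYS = ("azimuth_deg", "elevation_deg", "roll_deg", "fov_deg", "position_m", "image_size")


def camera_to_dict(params: CameraParams) -> dict:
    return {
        "azimuth_deg": float(params.azimuth),
        "elevation_deg": float(params.elevation),
        "roll_deg": float(params.roll),
        "fov_deg": float(params.fov),
        "position_m": [float(v) for v in params.position],
        "image_size": [int(v) for v in params.image_size],
    }


def camera_from_dict(d: dict) -> CameraParams:
    missing = [k for k in _CAM_KEYS if k not in d]
    if missing:
        raise KeyError(f"camera file missing keys: {missing}")
    return CameraParams(
        azimuth=float(d["azimuth_deg"]),
        elevation=float(d["elevation_deg"]),
        roll=float(d["roll_deg"]),
        fov=float(d["fov_deg"]),
        position=tuple(float(v) for v in d["position_m"]),
        image_size=tuple(int(v) for v in d["image_size"]),
    )


def save_camera(params: CameraParams, path) -> None:
    path = Path(path)
    d = camera_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_camera(path) -> CameraParams:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return camera_from_dict(d)
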