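"""Enumerate all pinhole cameras consistent with the lane vanishing point.

A single vanishing point v0 of the lane family leaves a one-parameter
ambiguity: for every azimuth there is exactly one (elevation, fov,
position) that reproduces v0 and the observed lane spacing.  The search
sweeps azimuth densely (default 0.5 deg over [1, 89] deg), solving each
stage in turn:

1. elevation - the direction from the principal point to the simulated
   lane vanishing point is fov-independent; bisect elevation until it
   matches the direction to the detected v0.
2. fov - the simulated vanishing point moves along the fixed ray from the
   principal point when zooming, so the focal length follows in closed
   form from the distance |v0 - centre|.
3. position - ray-trace the detected lanes onto the ground plane from a
   trial camera; the implied lane spacing scales linearly with camera
   distance, which pins the height, and alignment to the lane grid pins
   the lateral offset.

Identifiability conventions: the principal ray meets the ground at x = 0
(position along the track is not observable from infinite parallel
lines), and the lowest recovered lane is grid index 0 (which physical
lane is lane 0 is not observable either).  Roll is 0: the ground-plane
horizon of a broadcast camera is horizontal, which our rotation
composition guarantees by construction.

A selection constraint (second vanishing point, camera height, or
lateral offset) then picks one candidate, with linear interpolation
between the two bracketing azimuth samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .camera_model import (
    AtInfinity,
    CameraParams,
    ProjectionMatrix,
    build_projection,
    focal_from_fov,
    fov_from_focal,
    rotation_world_to_camera,
    vanishing_point_of_direction,
)
from .lane_detection import ImageLine, LaneSet, VanishingPoint
from .scene_model import TrackScene

__all__ = [
    "GeometrySearchConfig",
    "Candidate",
    "CandidateSet",
    "SelectionConstraint",
    "NoSolutionError",
    "EmptyCandidateSetError",
    "solve_elevation",
    "fit_fov",
    "solve_translation",
    "enumerate_candidates",
    "select_candidate",
    "project_lane_line",
    "lane_overlay_error",
]

LANE_DIRECTION = np.array([1.0, 0.0, 0.0])
CROSS_DIRECTION = np.array([0.0, 1.0, 0.0])


class NoSolutionError(ValueError):
    """A sweep stage has no solution at this azimuth."""


class EmptyCandidateSetError(RuntimeError):
    """No azimuth in the sweep produced a valid candidate."""

    def __init__(self, failures: dict):
        self.failures = failures
        super().__init__(f"no candidates; per-azimuth failures: {failures}")


@dataclass(frozen=True)
class GeometrySearchConfig:
    az_min: float = 1.0
    az_max: float = 89.0
    az_step: float = 0.5
    elevation_tol_deg: float = 1e-6
    fov_min: float = 0.1
    fov_max: float = 179.0
    vp_tol_px: float = 0.5  # candidate must reproject v0 within this

    @classmethod
    def from_dict(cls, d: dict) -> "GeometrySearchConfig":
        return replace(cls(), **d)


def _vp_offset_unit_focal(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Offset of the lane vanishing point from the principal point at focal 1.

    fov-independent up to this scale: the actual pixel offset is
    ``focal_px * offset``.
    """
    R = rotation_world_to_camera(azimuth_deg, elevation_deg, 0.0)
    h = R @ LANE_DIRECTION
    if abs(h[2]) < 1e-15:
        raise NoSolutionError("lane direction parallel to the image plane")
    return h[:2] / h[2]


def solve_elevation(azimuth: float, v0_direction, image_size) -> float:
    """Elevation whose simulated-VP direction from the principal point
    matches ``v0_direction`` at the given azimuth.

    ``v0_direction`` is the unit 2-vector from the image centre toward the
    detected v0 (image y down).  Solved by bisection on the signed angular
    mismatch to 1e-6 deg; monotonicity of the mismatch in elevation is
    checked at the bracket endpoints.

    Raises
    ------
    NoSolutionError
        No elevation in (0, 89) deg achieves the direction (e.g. the
        direction points below the horizon or is flipped 180 deg).
    """
    tgt = np.asarray(v0_direction, dtype=float)
    n = np.linalg.norm(tgt)
    if n == 0:
        raise NoSolutionError("v0 coincides with the principal point")
    tgt = tgt / n
    phi_target = math.atan2(tgt[1], tgt[0])

    def mismatch(el: float) -> float:
        off = _vp_offset_unit_focal(azimuth, el)
        return math.atan2(off[1], off[0]) - phi_target

    lo, hi = 0.0, 89.999
    g_lo, g_hi = mismatch(lo), mismatch(hi)
    if g_lo == 0.0:
        return lo
    if g_lo * g_hi > 0.0:
        raise NoSolutionError(
            f"no elevation in (0, 89) deg matches the v0 direction at azimuth {azimuth} deg"
        )
    if not (g_lo > g_hi or g_lo < g_hi):  # pragma: no cover - defensive
        raise NoSolutionError("degenerate elevation bracket")
    increasing = g_hi > g_lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = mismatch(mid)
        if (g > 0.0) == increasing:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)


def fit_fov(azimuth: float, elevation: float, v0, image_size,
            config: GeometrySearchConfig = GeometrySearchConfig()) -> float:
    """Field of view that lands the analytic lane VP exactly on v0.

    Closed form: the VP sits on the fixed ray from the principal point, at
    pixel distance ``focal_px * |offset@focal 1|``, so
    ``focal_px = |v0 - centre| / |offset|``.

    Raises
    ------
    NoSolutionError
        v0 at the principal point, direction-inconsistent (az, el), or a
        resulting fov outside (fov_min, fov_max).
    """
    w, h = image_size
    centre = np.array([w / 2.0, h / 2.0])
    dv = np.asarray(v0, dtype=float) - centre
    r = np.linalg.norm(dv)
    if r < 1e-9:
        raise NoSolutionError("v0 at the principal point: fov degenerate")
    off = _vp_offset_unit_focal(azimuth, elevation)
    m = np.linalg.norm(off)
    if m < 1e-15:
        raise NoSolutionError("simulated VP at the principal point")
    if float(dv @ off) <= 0.0:
        raise NoSolutionError("(azimuth, elevation) not direction-consistent with v0")
    focal_px = r / m
    fov = fov_from_focal(focal_px, w)
    if not (config.fov_min < fov < config.fov_max):
        raise NoSolutionError(f"fov {fov:.3f} deg outside valid range")
    return fov


def _fit_lane_grid(k_sorted: np.ndarray, gaps: np.ndarray):
    """Consensus fit of sorted lane slopes to a uniform grid with outliers.

    Detected lanes ray-trace to ground intercepts linear in their slopes
    ``k``; true lanes sit on an arithmetic grid (missing lanes leave
    integer-multiple gaps, spurious lanes sit off-grid).  Every
    (anchor lane, gap/m) pair proposes a unit spacing; the proposal with
    the most on-grid lanes (residual < 20% of the unit) wins and the unit
    is re-estimated by least squares over its inliers.

    Returns (unit, inlier mask, grid indices of inliers), or (None, ...)
    if no proposal explains at least two lanes.
    """
    n = len(k_sorted)
    units = {float(g / m) for g in gaps if g > 0 for m in (1, 2, 3)}
    # maximise inliers, then prefer the coarsest unit (any sub-multiple of
    # the true pitch fits equally well), then the smallest residual
    best = (1, -np.inf, np.inf, None, None)  # (n_in, unit, rss, mask, q)
    for u in units:
        if u <= 0:
            continue
        for a in range(n):
            rel = k_sorted - k_sorted[a]
            q = np.round(rel / u)
            res = np.abs(rel - q * u)
            mask = res < 0.2 * u
            # require distinct grid positions among inliers
            if len(np.unique(q[mask])) != mask.sum():
                continue
            cand = (int(mask.sum()), u, float((res[mask] ** 2).sum()), mask, q)
            if (cand[0], cand[1], -cand[2]) > (best[0], best[1], -best[2]):
                best = cand
    n_in, u, _, mask, q = best
    if mask is None or n_in < 2:
        return None, None, None
    # least-squares unit over inliers (q relative to the anchor)
    qi = q[mask]
    ki = k_sorted[mask]
    qi = qi - qi.min()
    A = np.column_stack([qi, np.ones_like(qi)])
    sol, *_ = np.linalg.lstsq(A, ki, rcond=None)
    unit = float(sol[0]) if sol[0] > 0 else u
    return unit, mask, qi.astype(int)


def _ray_directions(lanes: LaneSet, K: np.ndarray, R: np.ndarray) -> np.ndarray:
    """World-frame ray directions of one representative pixel per lane."""
    Kinv = np.linalg.inv(K)
    dirs = []
    for ln in lanes.lanes:
        u, v = ln.point
        dirs.append(R.T @ (Kinv @ np.array([u, v, 1.0])))
    return np.asarray(dirs)


def solve_translation(
    azimuth: float,
    elevation: float,
    fov: float,
    lanes: LaneSet,
    scene: TrackScene,
    image_size=(1280, 720),
) -> np.ndarray:
    """Camera position from lane spacing, with K and R fixed.

    Ray-tracing the detected lanes onto z = 0 gives lines parallel to the
    running direction whose y-intercepts are ``c_y - c_z * k_i`` with
    per-lane slopes ``k_i`` that depend only on K and R.  The spacing is
    linear in the camera height, so ``c_z = lane_width / median gap(k)``;
    aligning the recovered intercepts to the lane grid (lowest lane at
    y = 0) fixes ``c_y``, and the principal-ray-at-x=0 convention fixes
    ``c_x``.

    Raises
    ------
    NoSolutionError
        Any lane (or the principal ray) ray-traces on or above the horizon.
    """
    if len(lanes) < 2:
        raise NoSolutionError("need >= 2 lanes to solve the translation")
    w, h = image_size
    f = focal_from_fov(fov, w)
    K = np.array([[f, 0, w / 2.0], [0, f, h / 2.0], [0, 0, 1.0]])
    R = rotation_world_to_camera(azimuth, elevation, 0.0)
    dirs = _ray_directions(lanes, K, R)
    if np.any(dirs[:, 2] >= 0.0):
        raise NoSolutionError("a detected lane ray-traces above the horizon")
    k = dirs[:, 1] / dirs[:, 2]
    k_sorted = np.sort(k)
    gaps = np.diff(k_sorted)
    if len(gaps) == 0 or not np.any(gaps > 0):
        raise NoSolutionError("degenerate lane spacing")
    unit, inliers, q = _fit_lane_grid(k_sorted, gaps)
    if unit is None:
        raise NoSolutionError("lane slopes do not fit a uniform grid")
    cz = scene.lane_width / unit
    # ascending k means descending ground y; lane index counts y upward
    grid_y = scene.lane_width * (q.max() - q)
    cy = float(np.mean(grid_y + cz * k_sorted[inliers]))
    # principal ray pins x: camera view target sits at x = 0
    d_pp = R.T @ np.array([0.0, 0.0, 1.0])
    if d_pp[2] >= 0.0:
        raise NoSolutionError("principal ray does not meet the ground plane")
    cx = cz * d_pp[0] / d_pp[2]
    return np.array([cx, cy, cz])


@dataclass(frozen=True)
class Candidate:
    """One member of the camera family: full parameters plus its second VP."""

    params: CameraParams
    proj: ProjectionMatrix
    v1: tuple[float, float] | None  # image of the cross-lane direction

    @property
    def azimuth(self) -> float:
        return self.params.azimuth


@dataclass(frozen=True)
class CandidateSet:
    """The dense one-parameter camera family explaining one v0."""

    candidates: tuple[Candidate, ...]
    sweep_step: float
    v0: VanishingPoint
    lanes: LaneSet
    scene: TrackScene
    image_size: tuple[int, int]
    failures: dict

    def __len__(self) -> int:
        return len(self.candidates)

    def azimuths(self) -> np.ndarray:
        return np.array([c.azimuth for c in self.candidates])


def _candidate_at(
    azimuth: float,
    v0_xy: np.ndarray,
    lanes: LaneSet,
    scene: TrackScene,
    image_size,
    config: GeometrySearchConfig,
) -> Candidate:
    w, h = image_size
    centre = np.array([w / 2.0, h / 2.0])
    direction = v0_xy - centre
    el = solve_elevation(azimuth, direction, image_size)
    fov = fit_fov(azimuth, el, v0_xy, image_size, config)
    pos = solve_translation(azimuth, el, fov, lanes, scene, image_size)
    params = CameraParams(
        azimuth=azimuth, elevation=el, roll=0.0, fov=fov,
        position=tuple(pos), image_size=tuple(image_size),
    )
    proj = build_projection(params)
    vp = vanishing_point_of_direction(LANE_DIRECTION, proj)
    if isinstance(vp, AtInfinity) or np.linalg.norm(vp - v0_xy) > config.vp_tol_px:
        raise NoSolutionError("candidate fails to reproject v0 within tolerance")
    v1 = vanishing_point_of_direction(CROSS_DIRECTION, proj)
    v1_t = None if isinstance(v1, AtInfinity) else (float(v1[0]), float(v1[1]))
    return Candidate(params=params, proj=proj, v1=v1_t)


def enumerate_candidates(
    v0: VanishingPoint,
    lanes: LaneSet,
    scene: TrackScene,
    image_size=(1280, 720),
    config: GeometrySearchConfig = GeometrySearchConfig(),
) -> CandidateSet:
    """Sweep azimuth and build every camera consistent with v0.

    The sweep covers |azimuth| in [az_min, az_max] at az_step; the sign of
    the azimuth is fixed by which side of the principal point v0 lies on.
    Azimuths failing any stage are recorded in ``failures`` and skipped.

    Raises
    ------
    EmptyCandidateSetError
        No azimuth produced a candidate (carries the per-azimuth log).
    """
    if v0.at_infinity:
        raise NoSolutionError("v0 at infinity: camera family undefined")
    v0_xy = v0.xy
    w, h = image_size
    sign = 1.0 if v0_xy[0] >= w / 2.0 else -1.0
    azimuths = np.arange(config.az_min, config.az_max + 1e-9, config.az_step)
    out: list[Candidate] = []
    failures: dict[float, str] = {}
    for a in azimuths:
        az = sign * float(a)
        try:
            out.append(_candidate_at(az, v0_xy, lanes, scene, image_size, config))
        except NoSolutionError as e:
            failures[az] = str(e)
    if not out:
        raise EmptyCandidateSetError(failures)
    out.sort(key=lambda c: abs(c.azimuth))
    return CandidateSet(
        candidates=tuple(out), sweep_step=config.az_step, v0=v0,
        lanes=lanes, scene=scene, image_size=tuple(image_size), failures=failures,
    )


@dataclass(frozen=True)
class SelectionConstraint:
    """Exactly one auxiliary constraint that disambiguates the family."""

    v1: tuple[float, float] | None = None
    height: float | None = None
    lateral: float | None = None

    def __post_init__(self) -> None:
        active = sum(v is not None for v in (self.v1, self.height, self.lateral))
        if active != 1:
            raise ValueError("exactly one selection constraint must be active")

    def residual(self, cand: Candidate) -> float:
        """Signed residual; its zero crossing locates the solution."""
        if self.v1 is not None:
            if cand.v1 is None:
                return math.inf
            # v1 slides along the horizon as azimuth varies: compare x
            return cand.v1[0] - self.v1[0]
        if self.height is not None:
            return cand.params.position[2] - self.height
        return cand.params.position[1] - self.lateral


def select_candidate(
    cands: CandidateSet,
    constraint: SelectionConstraint,
    config: GeometrySearchConfig = GeometrySearchConfig(),
) -> CameraParams:
    """Pick the family member minimising the constraint residual.

    The residual's zero crossing between the two bracketing azimuth
    samples is located by linear interpolation and the candidate is
    rebuilt exactly at the interpolated azimuth.  Ties break toward the
    lower azimuth; a non-unimodal residual profile triggers a warning and
    returns the global minimum.
    """
    if len(cands) == 0:
        raise EmptyCandidateSetError(cands.failures)
    res = np.array([constraint.residual(c) for c in cands.candidates])
    absres = np.abs(res)
    finite = np.isfinite(absres)
    if not finite.any():
        raise NoSolutionError("constraint residual undefined on every candidate")
    best = int(np.flatnonzero(finite)[np.argmin(absres[finite])])

    # unimodality check on the |residual| profile
    fin = absres[finite]
    n_local_min = sum(
        1
        for i in range(1, len(fin) - 1)
        if fin[i] < fin[i - 1] and fin[i] <= fin[i + 1]
    )
    if n_local_min > 1:
        warnings.warn(
            "constraint residual not unimodal across the sweep; returning the global minimum",
            stacklevel=2,
        )
        return cands.candidates[best].params

    # interpolate the zero crossing of the signed residual around the minimum
    for j in (best - 1, best):
        if 0 <= j < len(cands) - 1:
            r0, r1 = res[j], res[j + 1]
            if np.isfinite(r0) and np.isfinite(r1) and r0 * r1 < 0.0:
                a0 = cands.candidates[j].azimuth
                a1 = cands.candidates[j + 1].azimuth
                az = a0 + (a1 - a0) * (-r0) / (r1 - r0)
                try:
                    return _candidate_at(
                        az, cands.v0.xy, cands.lanes, cands.scene,
                        cands.image_size, config,
                    ).params
                except NoSolutionError:  # pragma: no cover - fall back to sample
                    break
    return cands.candidates[best].params


# ---------------------------------------------------------------------------
# Overlay diagnostics


def project_lane_line(proj: ProjectionMatrix, y_m: float) -> ImageLine | None:
    """Image line of the world lane {y = y_m, z = 0}, or None if the lane
    lies entirely behind the camera.

    The depth of the lane point at parameter x is affine in x, so the
    visible half-line is found analytically and sampled well inside it.
    """
    # depth w(x) = a x + b from the projection's third row
    a = proj.P[2, 0]
    b = proj.P[2, 1] * y_m + proj.P[2, 3]
    if a == 0.0:
        if b <= 0:
            return None
        xs = np.array([-100.0, 100.0])
    else:
        x0 = -b / a  # w = 0 crossing
        sign = 1.0 if a > 0 else -1.0
        xs = x0 + sign * np.array([10.0, 300.0])
    pts3 = np.column_stack([xs, np.full(2, y_m), np.zeros(2)])
    hom = np.hstack([pts3, np.ones((2, 1))]) @ proj.P.T
    if np.any(hom[:, 2] <= 0):
        return None
    px = hom[:, :2] / hom[:, 2:3]
    if np.linalg.norm(px[1] - px[0]) < 1e-9:
        return None
    return ImageLine(point=px[0], direction=px[1] - px[0])


def lane_overlay_error(
    proj: ProjectionMatrix,
    scene: TrackScene,
    lanes: LaneSet,
    image_size=(1280, 720),
) -> float:
    """Mean pixel distance between detected lanes and the reprojected lane grid.

    Each detected lane is matched to its nearest reprojected scene lane;
    the distance is evaluated at two in-image sample points on the
    detected lane.
    """
    w, h = image_size
    proj_lines = []
    for k in range(scene.n_lanes):
        ln = project_lane_line(proj, k * scene.lane_width)
        if ln is not None:
            proj_lines.append(ln)
    if not proj_lines:
        return math.inf
    errs = []
    for det in lanes.lanes:
        samples = [det.point + s * det.direction for s in (-150.0, 150.0)]
        samples = [p for p in samples if 0 <= p[0] <= w and 0 <= p[1] <= h] or [det.point]
        e = min(
            float(np.mean([pl.distance_to(p) for p in samples])) for pl in proj_lines
        )
        errs.append(e)
    return float(np.mean(errs))
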