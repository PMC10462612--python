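"""Lane-line extraction and vanishing-point voting.

Pipeline: grayscale -> Canny edges -> probabilistic Hough segments ->
dominant-direction filter -> merge collinear segments into lanes -> vote
the main vanishing point v0 from pairwise lane intersections.

The vote is realised deterministically: all pairwise intersections are
grid-hashed at a configurable cell size (support-weighted), the modal
cell is taken, and the geometric median of the intersections around it
seeds a least-squares refinement over the lane lines consistent with it.
Near-parallel lane pairs contribute no vote (their intersection is
numerically unstable), and for a distant v0 the intersection cloud is
heavy-tailed along the lane direction, which is why the final estimate
comes from the lines rather than the intersections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from collections import Counter

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

__all__ = [
    "LineSegment",
    "ImageLine",
    "LaneSet",
    "VanishingPoint",
    "LaneDetectionConfig",
    "InsufficientLanesError",
    "detect_segments",
    "cluster_lanes",
    "analyze_frame",
    "estimate_vanishing_point",
    "smooth_vanishing_points",
]


class InsufficientLanesError(ValueError):
    """Fewer than two lanes survive filtering; no vanishing point possible."""


@dataclass(frozen=True)
class LaneDetectionConfig:
    """Tunable knobs of the lane detector.

    The Hough and clustering thresholds are defaults tuned on the synthetic
    renderer's fixtures (1280x720, ~3 px anti-aliased lane lines); all are
    exposed because broadcast footage varies.
    """

    canny_sigma: float = 1.5
    canny_low: float | None = 0.1
    canny_high: float | None = 0.25
    hough_threshold: int = 10
    hough_line_length: int = 60
    hough_line_gap: int = 8
    hough_seed: int = 0
    angle_bin_deg: float = 2.0       # histogram bin for the dominant direction
    angle_keep_deg: float = 20.0     # keep segments within +- this of the modal bin
                                     # (lane angles span ~15 deg in wide views;
                                     # clutter is rejected later by the VP gate)
    merge_dist_px: float = 8.0       # max centre-offset gap for merging into one lane
    vp_angle_gap_deg: float = 0.15   # about-VP angle gap separating two lanes
                                     # (above the ~0.09 deg between the two Canny
                                     # edges of one 3 px line, below typical
                                     # adjacent-lane gaps)
    vp_line_tol_frac: float = 0.03   # a segment's line must pass within this
                                     # fraction of the VP distance (plus 50 px)
    min_lane_support_px: float = 80.0  # drop merged lanes with less total length
    near_parallel_deg: float = 0.5   # pairs closer in angle cast no vote
    vote_cell_px: float = 10.0       # grid-hash cell for the majority vote
    vote_radius_px: float = 25.0     # inlier radius around the modal cell centre
    refine_band_px: float = 4.0      # half-width of the subpixel refinement band
    refine_iters: int = 4            # intensity-weighted refit passes (0 = off)

    @classmethod
    def from_dict(cls, d: dict) -> "LaneDetectionConfig":
        return replace(cls(), **d)


@dataclass(frozen=True)
class LineSegment:
    """A straight segment in image coordinates (pixels)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def angle(self) -> float:
        """Direction angle in degrees, folded to [0, 180)."""
        a = math.degrees(math.atan2(self.p1[1] - self.p0[1], self.p1[0] - self.p0[0]))
        return a % 180.0

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.p0) + np.asarray(self.p1))


@dataclass(frozen=True)
class ImageLine:
    """An infinite image line: a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray
    support: float = 0.0  # total segment length merged into this lane

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("line direction must be nonzero")
        d = d / n
        # canonical orientation: angle folded to [0, 180) so that signed
        # offsets are comparable across lines
        if d[1] < 0 or (d[1] == 0 and d[0] < 0):
            d = -d
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    @property
    def angle(self) -> float:
        return math.degrees(math.atan2(self.direction[1], self.direction[0])) % 180.0

    def offset_from(self, origin) -> float:
        """Signed perpendicular offset of the line from ``origin``."""
        rel = self.point - np.asarray(origin, dtype=float)
        return float(self.direction[0] * rel[1] - self.direction[1] * rel[0])

    def distance_to(self, pt) -> float:
        rel = np.asarray(pt, dtype=float) - self.point
        return abs(self.direction[0] * rel[1] - self.direction[1] * rel[0])


def intersect_lines(a: ImageLine, b: ImageLine) -> np.ndarray | None:
    """Intersection point of two image lines, or None if (near-)parallel."""
    d1, d2 = a.direction, b.direction
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-14:
        return None
    rel = b.point - a.point
    t = (rel[0] * d2[1] - rel[1] * d2[0]) / denom
    return a.point + t * d1


@dataclass(frozen=True)
class LaneSet:
    """Merged lane lines sorted by image position, with per-lane support."""

    lanes: tuple[ImageLine, ...]

    def __len__(self) -> int:
        return len(self.lanes)


@dataclass(frozen=True)
class VanishingPoint:
    """Voted main vanishing point v0 (may lie far outside the image).

    ``v0 is None`` marks a vanishing point at infinity (parallel lanes).
    """

    v0: tuple[float, float] | None
    n_votes: int = 0
    inlier_spread: float = 0.0

    @property
    def at_infinity(self) -> bool:
        return self.v0 is None

    @property
    def xy(self) -> np.ndarray:
        if self.v0 is None:
            raise ValueError("vanishing point at infinity has no coordinates")
        return np.asarray(self.v0, dtype=float)


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img[..., :3])
    return img.astype(float)


def detect_segments(image, config: LaneDetectionConfig = LaneDetectionConfig()) -> list[LineSegment]:
    """Extract straight-line segments via Canny + probabilistic Hough.

    Returns an empty list (not an exception) for blank/empty images.
    """
    img = _to_gray(image)
    if img.size == 0 or img.max() == img.min():
        return []
    edges = canny(
        img,
        sigma=config.canny_sigma,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
    )
    if not edges.any():
        return []
    lines = probabilistic_hough_line(
        edges,
        threshold=config.hough_threshold,
        line_length=config.hough_line_length,
        line_gap=config.hough_line_gap,
        rng=config.hough_seed,
    )
    return [
        LineSegment(p0=(float(p0[0]), float(p0[1])), p1=(float(p1[0]), float(p1[1])))
        for p0, p1 in lines
    ]


def _angle_diff(a: float, b: float) -> float:
    """Smallest difference between two undirected line angles (degrees)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _ls_vanishing_point(lines: list[ImageLine], weights=None) -> np.ndarray | None:
    """Weighted least-squares point minimising squared distances to lines."""
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for i, ln in enumerate(lines):
        nrm = np.array([-ln.direction[1], ln.direction[0]])
        w = 1.0 if weights is None else weights[i]
        A += w * np.outer(nrm, nrm)
        b += w * nrm * (nrm @ ln.point)
    if abs(np.linalg.det(A)) < 1e-12 * max(1.0, A.trace() ** 2):
        return None
    return np.linalg.solve(A, b)


def _rough_vanishing_point(
    lines: list[ImageLine], config: LaneDetectionConfig
) -> np.ndarray | None:
    """Robust concurrency point of the segment lines, used to guide clustering.

    Deterministic consensus search: every pair among the longest segments
    proposes an intersection; the hypothesis explaining the most total
    segment length (lines passing within a distance-scaled tolerance)
    wins and is refined by length-weighted least squares over its
    inliers.  Tens-of-pixels accuracy suffices here.  Returns None when
    the segments are (near-)parallel throughout.
    """
    if len(lines) < 3:
        return None
    top = sorted(lines, key=lambda l: -l.support)[:25]
    best_score, best_inliers = 0.0, None
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            if _angle_diff(top[i].angle, top[j].angle) < config.near_parallel_deg:
                continue
            p = intersect_lines(top[i], top[j])
            if p is None or not np.all(np.isfinite(p)) or np.abs(p).max() > 1e7:
                continue
            inliers = []
            score = 0.0
            for ln in lines:
                tol = 30.0 + config.vp_line_tol_frac * float(np.linalg.norm(p - ln.point))
                if ln.distance_to(p) <= tol:
                    inliers.append(ln)
                    score += ln.support
            if score > best_score:
                best_score, best_inliers = score, inliers
    if best_inliers is None or len(best_inliers) < 3:
        return None
    return _ls_vanishing_point(best_inliers, [ln.support for ln in best_inliers])


def _refine_lane(line: ImageLine, image: np.ndarray, band: float) -> ImageLine:
    """Subpixel refit: intensity-weighted TLS over a band around the line.

    The centreline of an anti-aliased bright lane line is its intensity
    centroid; pixels within ``band`` of the current estimate are weighted
    by their brightness above the band's median (the local background).
    """
    h, w = image.shape[:2]
    # sample along the in-image extent of the line
    ts = []
    for bx, by in ((0, None), (w - 1, None), (None, 0), (None, h - 1)):
        d = line.direction
        p = line.point
        if bx is not None and abs(d[0]) > 1e-12:
            ts.append((bx - p[0]) / d[0])
        if by is not None and abs(d[1]) > 1e-12:
            ts.append((by - p[1]) / d[1])
    if len(ts) < 2:
        return line
    t_lo, t_hi = min(ts), max(ts)
    x_lo = np.clip(line.point + t_lo * line.direction, [0, 0], [w - 1, h - 1])
    x_hi = np.clip(line.point + t_hi * line.direction, [0, 0], [w - 1, h - 1])
    pad = int(math.ceil(band)) + 1
    c0 = max(0, int(min(x_lo[0], x_hi[0])) - pad)
    c1 = min(w - 1, int(max(x_lo[0], x_hi[0])) + pad)
    r0 = max(0, int(min(x_lo[1], x_hi[1])) - pad)
    r1 = min(h - 1, int(max(x_lo[1], x_hi[1])) + pad)
    if c1 <= c0 or r1 <= r0:
        return line
    X, Y = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    dx = X - line.point[0]
    dy = Y - line.point[1]
    dist = np.abs(line.direction[0] * dy - line.direction[1] * dx)
    mask = dist <= band
    if mask.sum() < 10:
        return line
    vals = image[r0 : r1 + 1, c0 : c1 + 1][mask]
    wgt = np.clip(vals - np.median(vals), 0.0, None)
    if wgt.sum() < 1e-9:
        return line
    xs = X[mask].astype(float)
    ys = Y[mask].astype(float)
    cx = float((xs * wgt).sum() / wgt.sum())
    cy = float((ys * wgt).sum() / wgt.sum())
    rel = np.column_stack([xs - cx, ys - cy]) * np.sqrt(wgt)[:, None]
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    return ImageLine(point=np.array([cx, cy]), direction=vt[0], support=line.support)


def cluster_lanes(
    segments: list[LineSegment],
    config: LaneDetectionConfig = LaneDetectionConfig(),
    *,
    origin=None,
    image=None,
) -> LaneSet:
    """Filter segments to the dominant direction family and merge them into lanes.

    The dominant direction is the modal bin of a length-weighted angular
    histogram; segments within ``angle_keep_deg`` of it survive.  Survivors
    are merged by the perpendicular offset of their infinite line from the
    image centre, and each merged lane is a length-weighted total
    least-squares line through its segments' endpoints.

    Raises
    ------
    InsufficientLanesError
        If fewer than two lanes remain.
    """
    if not segments:
        raise InsufficientLanesError("no segments to cluster")
    angles = np.array([s.angle for s in segments])
    lengths = np.array([s.length for s in segments])

    nbins = max(1, int(round(180.0 / config.angle_bin_deg)))
    bins = (angles // config.angle_bin_deg).astype(int) % nbins
    weight = Counter()
    for b, l in zip(bins, lengths):
        weight[int(b)] += l
    modal_bin = max(weight, key=weight.get)
    modal_angle = (modal_bin + 0.5) * config.angle_bin_deg
    keep = [
        s
        for s, a in zip(segments, angles)
        if _angle_diff(a, modal_angle) <= config.angle_keep_deg + config.angle_bin_deg / 2
    ]
    if origin is None:
        pts = np.array([s.midpoint for s in segments])
        origin = pts.mean(axis=0)
    origin = np.asarray(origin, dtype=float)

    def seg_line(s: LineSegment) -> ImageLine:
        return ImageLine(
            point=np.asarray(s.p0, dtype=float),
            direction=np.asarray(s.p1, dtype=float) - np.asarray(s.p0, dtype=float),
            support=s.length,
        )

    # Lane membership is decided about a vanishing point when one exists:
    # all lanes converge there, so the angle of a segment's midpoint about
    # it separates lanes far more reliably than any offset measured from a
    # fixed origin (whose lever arm amplifies angle noise).  The VP guess
    # is itself refined from the fitted lanes and the clustering repeated:
    # lane-line angles are much more accurate than segment angles, which
    # shrinks the VP's lateral error below what merges adjacent lanes.
    def _cluster_about_vp(v0g: np.ndarray) -> list[list[LineSegment]]:
        items = []
        for s in keep:
            ln = seg_line(s)
            mid = s.midpoint
            dist_vp = float(np.linalg.norm(mid - v0g))
            if ln.distance_to(v0g) > 50.0 + config.vp_line_tol_frac * dist_vp:
                continue  # clutter: right direction, wrong place
            ang = math.degrees(math.atan2(mid[1] - v0g[1], mid[0] - v0g[0])) % 180.0
            items.append((ang, s))
        items.sort(key=lambda t: t[0])
        out: list[list[LineSegment]] = []
        last_a = None
        for a, s in items:
            if last_a is None or a - last_a > config.vp_angle_gap_deg:
                out.append([])
            out[-1].append(s)
            last_a = a
        return out

    v0_guess = _rough_vanishing_point([seg_line(s) for s in keep], config)
    clusters: list[list[LineSegment]] = []
    if v0_guess is not None:
        for _ in range(3):
            clusters = _cluster_about_vp(v0_guess)
            if len(clusters) < 2:
                break
            fitted = [_fit_cluster(cl) for cl in clusters]
            v0_new = _ls_vanishing_point(fitted, [ln.support for ln in fitted])
            if v0_new is None or not np.all(np.isfinite(v0_new)):
                break
            if np.linalg.norm(v0_new - v0_guess) < 1.0:
                v0_guess = v0_new
                clusters = _cluster_about_vp(v0_guess)
                break
            v0_guess = v0_new
    if len(clusters) < 2:
        # parallel lanes (VP at infinity) or too few assignments: fall back
        # to 1D clustering on the signed offset of each segment's line
        items = sorted(
            ((seg_line(s).offset_from(origin), s) for s in keep), key=lambda t: t[0]
        )
        clusters = []
        last_off = None
        for off, s in items:
            if last_off is None or off - last_off > config.merge_dist_px:
                clusters.append([])
            clusters[-1].append(s)
            last_off = off

    clusters = [sub for cl in clusters for sub in _split_cluster(cl)]
    clusters = _merge_coincident_clusters(clusters)
    lanes = [_fit_cluster(cl) for cl in clusters]
    # absolute and relative support gates: clutter fits carry an order of
    # magnitude less merged segment length than true lanes
    med_sup = float(np.median([ln.support for ln in lanes])) if lanes else 0.0
    floor = max(config.min_lane_support_px, 0.1 * med_sup)
    strong = [ln for ln in lanes if ln.support >= floor]
    if len(strong) >= 2:
        lanes = strong
    if image is not None and config.refine_iters > 0:
        img = _to_gray(image)
        # keep the refinement band inside half the closest lane separation
        # so tightly packed lanes do not pull each other's fit
        band = config.refine_band_px
        if len(lanes) >= 2:
            seps = []
            for i, ln in enumerate(lanes):
                d = min(
                    other.distance_to(ln.point)
                    for j, other in enumerate(lanes)
                    if j != i
                )
                seps.append(d)
            band = float(np.clip(0.45 * float(np.median(seps)), 2.0, config.refine_band_px))
        for _ in range(config.refine_iters):
            lanes = [_refine_lane(ln, img, band) for ln in lanes]
    lanes = _dedupe_lanes(lanes)
    lanes.sort(key=lambda ln: ln.offset_from(origin))
    if len(lanes) < 2:
        raise InsufficientLanesError(f"only {len(lanes)} lane(s) after clustering")
    return LaneSet(lanes=tuple(lanes))


def _cluster_residual(cl: list[LineSegment], line: ImageLine) -> float:
    """Length-weighted RMS perpendicular offset of segment midpoints."""
    num = 0.0
    den = 0.0
    for s in cl:
        d = line.distance_to(s.midpoint)
        num += s.length * d * d
        den += s.length
    return math.sqrt(num / den) if den > 0 else 0.0


def _split_cluster(cl: list[LineSegment], max_rms: float = 1.0, depth: int = 0) -> list[list[LineSegment]]:
    """Recursively split clusters whose line fit straddles several lanes.

    A clean anti-aliased lane fits with sub-pixel residual; a cluster that
    merged adjacent (tightly spaced) lanes shows a residual near the lane
    separation.  Such clusters are split at the largest gap in the signed
    perpendicular offsets of their segment midpoints.
    """
    if len(cl) < 2 or depth >= 5:
        return [cl]
    line = _fit_cluster(cl)
    if _cluster_residual(cl, line) <= max_rms:
        return [cl]
    offs = [
        (float(line.direction[0] * (s.midpoint[1] - line.point[1])
               - line.direction[1] * (s.midpoint[0] - line.point[0])), s)
        for s in cl
    ]
    offs.sort(key=lambda t: t[0])
    gaps = [offs[i + 1][0] - offs[i][0] for i in range(len(offs) - 1)]
    k = int(np.argmax(gaps))
    if gaps[k] < 0.5:  # no structure to split on
        return [cl]
    left = [s for _, s in offs[: k + 1]]
    right = [s for _, s in offs[k + 1 :]]
    if left and right:
        # the two Canny edges of one ~3 px lane line also show up as two
        # sub-clusters; only a split into genuinely separate lanes stands
        l_fit = _fit_cluster(left)
        r_fit = _fit_cluster(right)
        if l_fit.distance_to(r_fit.point) < 3.2:
            return [cl]
    return _split_cluster(left, max_rms, depth + 1) + _split_cluster(right, max_rms, depth + 1)


def _merge_coincident_clusters(
    clusters: list[list[LineSegment]], sep_px: float = 4.0, max_angle_deg: float = 0.5
) -> list[list[LineSegment]]:
    """Merge clusters whose fitted lines nearly coincide.

    The two Canny edges of one lane line often arrive as two clusters
    ~3 px apart; refitting their union recovers the centreline, whereas
    keeping either edge alone would bias the lane by half the line width.
    """
    work = [(cl, _fit_cluster(cl)) for cl in clusters]
    merged = True
    while merged:
        merged = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                fi, fj = work[i][1], work[j][1]
                if (
                    _angle_diff(fi.angle, fj.angle) < max_angle_deg
                    and fi.distance_to(fj.point) < sep_px
                ):
                    union = work[i][0] + work[j][0]
                    work[i] = (union, _fit_cluster(union))
                    del work[j]
                    merged = True
                    break
            if merged:
                break
    return [cl for cl, _ in work]


def _fit_cluster(cl: list[LineSegment]) -> ImageLine:
    """Length-weighted total least-squares line through a cluster's endpoints."""
    pts = []
    w = []
    for s in cl:
        pts.append(s.p0)
        pts.append(s.p1)
        w.append(s.length)
        w.append(s.length)
    pts = np.asarray(pts, dtype=float)
    w = np.asarray(w, dtype=float)
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    rel = (pts - centroid) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    return ImageLine(
        point=centroid, direction=vt[0], support=float(sum(s.length for s in cl))
    )


def _dedupe_lanes(
    lanes: list[ImageLine], min_sep_px: float = 3.0, max_angle_deg: float = 1.0
) -> list[ImageLine]:
    """Collapse lanes whose refined lines coincide (duplicate detections)."""
    kept: list[ImageLine] = []
    for ln in sorted(lanes, key=lambda l: -l.support):
        if any(
            _angle_diff(ln.angle, k.angle) < max_angle_deg
            and k.distance_to(ln.point) < min_sep_px
            for k in kept
        ):
            continue
        kept.append(ln)
    return kept


def analyze_frame(
    image, config: LaneDetectionConfig = LaneDetectionConfig()
) -> tuple[LaneSet, "VanishingPoint"]:
    """Convenience pipeline: segments -> lanes (subpixel-refined) -> v0."""
    segments = detect_segments(image, config)
    lanes = cluster_lanes(segments, config, image=image)
    return lanes, estimate_vanishing_point(lanes, config)


def _geometric_median(pts: np.ndarray, *, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Weiszfeld's algorithm; deterministic and robust to outliers."""
    x = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - x, axis=1)
        if np.any(d < 1e-12):
            return pts[np.argmin(d)]
        w = 1.0 / d
        x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def estimate_vanishing_point(
    lanes: LaneSet, config: LaneDetectionConfig = LaneDetectionConfig()
) -> VanishingPoint:
    """Majority-vote the main vanishing point from pairwise lane intersections.

    Raises
    ------
    InsufficientLanesError
        Fewer than two lanes.
    """
    if len(lanes) < 2:
        raise InsufficientLanesError("need >= 2 lanes to vote a vanishing point")
    pts = []
    wts = []
    ls = lanes.lanes
    for i in range(len(ls)):
        for j in range(i + 1, len(ls)):
            if _angle_diff(ls[i].angle, ls[j].angle) < config.near_parallel_deg:
                continue
            p = intersect_lines(ls[i], ls[j])
            if p is not None and np.all(np.isfinite(p)):
                pts.append(p)
                wts.append(min(ls[i].support, ls[j].support))
    if not pts:
        # all pairs below the near-parallel voting threshold: fall back to
        # the least-squares concurrency point of the lane lines, which is
        # still well-conditioned laterally; truly parallel lanes stay at
        # infinity
        v0 = _ls_vanishing_point(list(ls), [ln.support for ln in ls])
        if v0 is None or not np.all(np.isfinite(v0)) or np.abs(v0).max() > 1e7:
            return VanishingPoint(v0=None, n_votes=0, inlier_spread=float("inf"))
        spread = float(np.sqrt(np.mean([ln.distance_to(v0) ** 2 for ln in ls])))
        return VanishingPoint(v0=(float(v0[0]), float(v0[1])), n_votes=len(ls), inlier_spread=spread)
    pts = np.asarray(pts)

    wts = np.asarray(wts, dtype=float)
    if not np.any(wts > 0):
        wts = np.ones(len(pts))
    cell = config.vote_cell_px
    keys = np.floor(pts / cell).astype(np.int64)
    counts = Counter()
    for key, w in zip(map(tuple, keys), wts):
        counts[key] += w
    modal_key = max(counts, key=lambda k: (counts[k], -k[0], -k[1]))
    centre = (np.asarray(modal_key, dtype=float) + 0.5) * cell
    d = np.linalg.norm(pts - centre, axis=1)
    inliers = pts[d <= config.vote_radius_px]
    if len(inliers) == 0:
        inliers = pts[[int(np.argmin(d))]]
    v0 = _geometric_median(inliers)
    spread = float(np.sqrt(np.mean(np.sum((inliers - v0) ** 2, axis=1))))
    # The intersection cloud is heavy-tailed along the lane direction when
    # v0 is distant (small pairwise angles), so the median of intersections
    # is only the robust seed: the final v0 is the least-squares
    # concurrency point of the lanes consistent with it.  Outlier lanes
    # (rejected by the vote) stay excluded by the distance gate.
    for gate_frac in (0.01, 0.005, 0.002):
        r_v0 = float(np.mean([np.linalg.norm(ln.point - v0) for ln in ls]))
        gate = 3.0 + gate_frac * r_v0
        inlier_lanes = [ln for ln in ls if ln.distance_to(v0) <= gate]
        if len(inlier_lanes) < 2:
            break
        v0_ls = _ls_vanishing_point(inlier_lanes, [ln.support for ln in inlier_lanes])
        if v0_ls is None or not np.all(np.isfinite(v0_ls)) or np.abs(v0_ls).max() > 1e7:
            break
        v0 = v0_ls
    return VanishingPoint(v0=(float(v0[0]), float(v0[1])), n_votes=len(inliers), inlier_spread=spread)


def smooth_vanishing_points(
    sequence: list[VanishingPoint], window: int = 5
) -> list[VanishingPoint]:
    """Per-coordinate sliding median over a frame sequence.

    Frames whose vanishing point is missing/at infinity are filled from the
    median of the valid points inside their window.

    Raises
    ------
    ValueError
        Every frame in the sequence is missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    valid = [vp.v0 is not None for vp in sequence]
    if not any(valid):
        raise ValueError("all vanishing points missing; nothing to smooth")
    n = len(sequence)
    half = window // 2
    out: list[VanishingPoint] = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        pts = np.array([sequence[j].xy for j in range(lo, hi) if valid[j]])
        if len(pts) == 0:  # widen until a valid neighbour appears
            k = half
            while len(pts) == 0:
                k += 1
                lo, hi = max(0, i - k), min(n, i + k + 1)
                pts = np.array([sequence[j].xy for j in range(lo, hi) if valid[j]])
        med = np.median(pts, axis=0)
        src = sequence[i]
        out.append(
            VanishingPoint(
                v0=(float(med[0]), float(med[1])),
                n_votes=src.n_votes,
                inlier_spread=src.inlier_spread,
            )
        )
    return out
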