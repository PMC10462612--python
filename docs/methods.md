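# Methods

## Camera model and conventions

The camera is a pinhole with square pixels, zero skew and the principal
point at the exact centre of the frame, so the intrinsics reduce to the
horizontal field of view: `f_px = (W/2) / tan(fov/2)`. Extrinsics are a
pan/tilt/roll rotation plus a position. The world frame is right-handed
with x along the lanes toward the finish, y across the lanes and z up;
lane line k is `{y = 1.22 k, z = 0}` (the standardised lane width, default
1.22 m, nine lane lines bounding eight lanes).

Rotations compose world→camera as `R = R_roll(optical axis) ·
R_tilt(camera x) · R_pan(world z)` applied to coordinates, with a base
alignment that points the optical axis down the lanes at zero pan/tilt.
Two properties follow by construction and are verified as invariants:

* vanishing points depend only on `K R`, never on the position;
* at roll = 0 the two ground-plane vanishing points share the same image
  row — the horizon is horizontal, which is what broadcast framing shows.

Projection follows the standard column convention `p = P (X,Y,Z,1)ᵀ`.
Angles are degrees at every interface and radians internally.

### Identifiability

Infinite parallel lanes leave two coordinates unobservable: the position
*along* the lane direction, and *which* physical lane line is which. Both
are fixed by convention: the principal ray meets the ground at x = 0 (the
camera "view target" anchors the origin along the track), and the lane
with the smallest recovered y is grid index 0. The synthetic ground-truth
camera generator obeys the same conventions so recovered and true
positions are directly comparable; for real footage the conventions only
shift the world origin.

## Lane detection

Grayscale → Canny → probabilistic Hough yields line segments (all
thresholds in `LaneDetectionConfig`; the Hough sampler is explicitly
seeded so detection is deterministic). A length-weighted angular histogram
(2° bins) keeps the dominant direction family within ±20° — lane angles
span roughly 15° in wide views, and remaining clutter is rejected later by
a geometric gate rather than by direction.

Segments are grouped into lanes about a rough vanishing point: every pair
among the 25 longest segments proposes an intersection, the proposal whose
line passes near the most total segment length wins, and its inliers are
refined by weighted least squares. The angle of each segment midpoint
about this point separates lanes far more reliably than any offset
measured from a fixed origin, whose lever arm amplifies segment-angle
noise; the assignment is iterated, re-estimating the vanishing point from
the fitted lane lines, whose angles are an order of magnitude more
accurate than segment angles. Clusters with a high perpendicular fit
residual are split at the largest midpoint gap (tightly spaced lanes merge
otherwise), clusters whose fitted lines nearly coincide are re-merged —
the two Canny edges of one ~3 px line otherwise appear as two lanes ~3 px
apart, and keeping either edge alone would bias the lane by half the line
width. Each lane is finally refined to sub-pixel accuracy as the
intensity-weighted total-least-squares line over a band around it (band
adapted to half the closest lane separation so neighbours do not pull the
fit), and lanes with less than 10% of the median support are dropped as
clutter.

### The vanishing-point vote

Pairwise lane intersections (pairs closer than 0.5° in angle are excluded
as numerically unstable) are grid-hashed at 10 px, weighted by lane
support; the modal cell's neighbourhood gives a robust seed via the
geometric median. The *final* v₀ is the support-weighted least-squares
concurrency point of the lanes consistent with that seed, re-gated
iteratively. The reason for the two stages: the vote is what rejects
outlier lanes, but for a distant v₀ the intersection cloud is heavy-tailed
*along* the lane direction and the median of intersections alone was off
by over 100 px in configurations where the least-squares point over the
lane lines is accurate to ~0.1 px. When every pair is below the
near-parallel threshold the least-squares point is still attempted
directly; a singular system reports a vanishing point at infinity.

Across frames, `smooth_vanishing_points` applies a per-coordinate sliding
median (default window 5) and fills missing frames from their neighbours.

## The one-parameter camera family

For each azimuth on the sweep (0.5° steps over |azimuth| ∈ [1°, 89°]; the
sign follows which side of the principal point v₀ lies on):

1. **Elevation** by bisection (to 1e-6°) on the angular mismatch between
   the simulated vanishing-point direction — which is independent of fov —
   and the direction to the detected v₀. Under our rotation composition
   the offset at unit focal length is `(tan az / cos el, −tan el)`, so a
   closed form exists (`sin el = −(dy/dx) tan az`); the bisection route is
   kept as the implementation and the closed form serves as an independent
   oracle in the tests.
2. **Fov** in closed form: the vanishing point sits on a fixed ray from
   the principal point and its distance is proportional to the focal
   length.
3. **Position**: one representative pixel per detected lane back-projects
   to a ground intercept `c_y − c_z·k_i` whose slope `k_i` depends only on
   K and R. True lanes make the sorted `k_i` an arithmetic grid; the unit
   spacing is fitted by a consensus search over (anchor lane, gap/m)
   proposals that tolerates missing and spurious lanes, preferring the
   coarsest unit among maximal-inlier proposals because every sub-multiple
   of the true pitch fits equally well. The camera height is
   `lane_width / unit`, the lateral offset aligns the inliers to the grid,
   and the view-target convention fixes x.

Candidates failing any stage (or failing to reproject v₀ within 0.5 px)
are dropped with a per-azimuth log. Each candidate records its second
vanishing point v₁. Selection minimises a signed residual — v₁ position,
camera height, or lateral offset — locating the zero crossing between the
two bracketing azimuth samples by linear interpolation and rebuilding the
candidate exactly at the interpolated azimuth. Ties break toward the lower
azimuth; a non-unimodal residual (possible for the height constraint,
whose value is not monotone along the candidate curve) warns and returns
the global minimum.

## Pose-audit metrics

Per frame, given a reference 2D skeleton (17 joints, human3.6m-style
order), a predicted 3D skeleton and the camera: the predicted supporting
foot (lowest 3D ankle) selects the reference ankle pixel, which is
ray-traced to the ground to place the skeleton; the skeleton is scaled
about the contact joint until its projected height matches the reference
(bisection); the projection is aligned to the reference by closed-form
least-squares scale + translation (no rotation); then

* reprojection error: mean per-joint pixel offset, all 17 joints equally
  weighted;
* millimetre approximation: pixel error × (athlete height, default
  1800 mm, config) / reference pixel height — an image-scale conversion,
  not a true 3D distance;
* 2D knee error: |interior knee angle difference|, averaged over sides;
* approximate 3D knee error: the lower leg is rotated ±1° (central
  difference, config) about the flexion axis (normal of the
  hip–knee–ankle plane), both perturbations are projected, and the 2D
  error is divided by the sensitivity `|Δ2D| / |Δ3D|`. The realised 3D
  change is used in the denominator rather than the nominal ±1° because
  the interior angle folds at 180° for a near-straight leg. Sensitivities
  below 0.05 (near-frontal viewing; the 2D angle carries almost no
  information) cap the estimate and set a flag.

The audit evaluates touch-down frames: ray-tracing an airborne foot to the
ground would displace the skeleton along the viewing ray, so the
noise-free self-consistency (all metrics exactly zero) holds only when the
supporting foot actually touches. `detect_touchdown_frames` finds those
frames from 2D alone: a planted foot is world-stationary, so the per-frame
absolute ankle displacement (normalised by a smoothed skeleton height)
drops to zero through the stance, while the ankle is also near its lowest
pelvis-relative image position over a step-long window. The first frame of
each qualifying run is the touch-down; a fully-qualifying (stationary)
sequence collapses to its midpoint. The depth tolerance is deliberately
loose (7% of height) because perspective tilts the stance plateau; the
velocity gate carries the discrimination. Pelvis and height references are
smoothed over ~a step because the pelvis bounces and the pixel height
breathes with the pose. The detector is validated against the generator's
scripted contacts to ±1 frame over several camera placements; panning
footage would need stabilisation upstream, since camera motion is not
observable from a skeleton sequence alone.

### Correction strategies

Home-stretch athletes run straight at the finish line; two strategies
inject that knowledge into predictions that lack it. **Rotation
knowledge** re-yaws each skeleton about the vertical through its contact
so the hip-line perpendicular faces +x. **Movement knowledge**
straightens the predicted path: a curved lifted trajectory (the panning
camera changes the athlete-to-camera orientation and the lifter follows
it) both displaces and re-orients the skeletons, so the strategy fits a
total-least-squares line to the *predicted* ground contacts, re-yaws each
skeleton by the local path tangent's deviation from that line, and
projects the anchors onto it. The translation component alone would be
invisible to the metrics — the per-frame similarity alignment absorbs it —
which is why the tangent re-orientation is part of our reading of "path
straightening". `straighten_path` as a standalone operation remains purely
translational.

## Synthetic data

The generator emulates the study conditions end to end with no external
data:

* **Track renders**: anti-aliased lane lines (default 3 px wide) on a
  textured background (vertical luminance gradient + seeded Gaussian
  noise) so the edge detector faces non-trivial input; the analytic image
  lines and vanishing point are recorded pre-distortion. An optional
  radial distortion (k1, k2) warps the rendered image only — the
  calibration path stays pinhole, mirroring its modelling scope, which
  enables the robustness experiment (recovery error vs k1; position error
  stays within 2% of distance up to k1 = −0.1, the documented level).
* **Cameras**: `sample_broadcast_camera` draws positions from a
  stands-like box (x ∈ [−55, 25], y ∈ [−45, −12], z ∈ [5, 12] m), a view
  target on the track at x = 0, and a field of view that makes the lane
  grid fill 35–80% of the frame height, clipped to az ∈ [15°, 75°],
  el ∈ [3°, 30°], fov ∈ [5°, 40°]. The fov–distance correlation is how
  PTZ operators actually frame the home stretch; sampling them
  independently produces frames no broadcast shows (nine lanes compressed
  into ~80 px near the horizon), which are unresolvable at 1280×720.
* **Runner**: a 17-joint kinematic template (not a biomechanical model):
  the pelvis advances at 7.2 m/s with a 3.6 m gait cycle (two 1.8 m
  steps, 2 cycles/s, 50 fps), 20% stance fraction, 3 cm vertical bounce;
  feet are planted exactly at scripted contacts and swing linearly with a
  sinusoidal 25 cm lift; knees come from two-link inverse kinematics
  (thigh 0.50 m, shank 0.48 m) bending forward; arms swing in
  counter-phase. The stride/leg proportions are chosen so the planted-foot
  constraint stays within leg reach — the template has no heel-off, so an
  overlong stride would stretch the shank through the IK clamp. Touch-down
  frames and ground anchors are recorded exactly.
* **Corruptions** emulate pose-estimator error modes: Gaussian 2D joint
  jitter; a fixed knee-flexion bias; a linear yaw drift; and a curved
  trajectory (lateral arc plus the tangent yaw a curved lift implies).
  Clean pairs always satisfy `2D == project(3D)` bit-exactly.

## What the tests do and do not show

All pipelines are validated on these synthetic conditions: exact
ground-truth closure, camera recovery within 2% of distance / 0.5° /
2% fov on at least 48 of 50 seeded broadcast renders, metric
self-consistency and noise-response (the 2 px jitter response matches the
Rayleigh mean σ√(π/2) within 5% — the expected ratio is √(31/34) ≈ 0.955
after the similarity alignment removes 3 of 34 degrees of freedom), and
robustness to 20% outlier lanes and render-time lens distortion. Real
broadcast frames add phenomena the renderer does not model — athletes and
infield clutter occluding lanes, worn or curved markings, interlacing and
compression artefacts, actual lens systems, and pose estimators whose
error modes are richer than the parametric corruptions — so the synthetic
pass rates bound the method's numerical behaviour, not its field accuracy.

## Numerical choices

* Elevation bisection to 1e-6°; scale matching to 1e-3 px inside the
  audit; candidate v₀ tolerance 0.5 px.
* Degenerate inputs raise typed errors (points on the principal plane,
  rays missing the ground, fov outside (0, 180), coincident joints,
  all-parallel lanes → at-infinity result rather than an exception).
* Every stochastic component takes an explicit seed (Hough sampler, noise
  generators, camera sampler); all generators are pure functions of
  (config, seed).

## Known limitations

* Straight home stretch only; bends break the parallel-line model.
* Elevations below ~6° compress the far lanes under ~4 px spacing at
  1280×720 — below the resolving power of any line detector — and are the
  residual failure mode of the recovery benchmark.
* Absolute x and absolute lane index are conventions, not measurements.
* The millimetre reprojection figure is an image-scale approximation; a
  true 3D error would require 3D ground truth.
* The touch-down detector assumes a (quasi-)static camera or stabilised
  2D sequences.
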