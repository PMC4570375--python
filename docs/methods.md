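# Methods

This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Background model

The scene is backlit and unimodal: each pixel's fly-free brightness is a
single Gaussian whose location and scale we estimate robustly as the
temporal median μ and the scaled median absolute deviation
σ = c·med|Iₜ − μ|, c = 1/Φ⁻¹(3/4) ≈ 1.4826 (the factor that makes the MAD
a consistent estimate of a Gaussian standard deviation). Robust statistics
matter because flies traverse pixels during the fitting window; a fly
occupying a pixel in under half the warmup frames leaves the median
untouched, where a mean/SD model would be biased.

The foreground test is one-sided by default (`polarity: dark`): pixel p is
foreground when μ(p) − I(p) > N·σ(p). Flies are darker than the plate; a
symmetric test would also fire on bright noise excursions. `bright` and
`both` polarities exist for other imaging geometries.

Numerical choices:

* **σ floor (1 intensity unit).** On noiseless synthetic input the fitted
  MAD is exactly zero and the threshold N·σ would be vacuous. The floor is
  applied when thresholding, not stored, so the fitted model still reports
  the honest σ.
* **Selective update.** Every `update_period` frames (default 100), μ at
  *background-classified* pixels is blended toward the current frame with
  rate α = 0.05; foreground pixels are frozen. This prevents a stopped fly
  from entering the background ("phantoms"). σ is deliberately not
  re-estimated from single frames: one frame contributes no robust scale
  information, and blending σ toward the instantaneous |I − μ| would decay
  it toward zero on a static scene. σ is a sequence statistic; it is
  refreshed only by refitting. The cost is that slow changes in noise level
  are not tracked between refits — acceptable under screened backlighting,
  the regime this pipeline targets.
* **Pre-filter.** Frames are converted to grayscale by channel averaging
  and smoothed with a Gaussian of sd 1 px before any processing.

## Area model and validation

Segmented elements are validated by a Laplace-style area likelihood
p(x) = exp(−|πab − μ_areas|/σ_areas). Two consistency choices:

* The pipeline fits (μ_areas, σ_areas) on the **ellipse areas** πab of
  warmup detections, not on raw pixel counts. For a thresholded Gaussian
  blob the pixel-count area exceeds the 2σ-ellipse area by a
  truncation-dependent factor (~25 % at typical operating points); mixing
  the two scales would bias every likelihood. The plain moment formulas
  (mean, population variance) operate on whatever areas they are given.
* σ_areas is floored at a fraction of μ_areas (default 0.15) in the
  pipeline. Near-identical flies — the synthetic case exactly — give a
  vanishing area variance, making the likelihood an indicator function and
  the validation unstable. The floor encodes a realistic ≥15 % size spread.

Re-segmentation search: when a component's likelihood is below the
acceptance floor e⁻³, the local threshold N is stepped **geometrically**
(N·1.6ᵏ, k ≤ 8) upward for oversized blobs and downward for undersized
ones. Geometric stepping is required because the saddle between two
touching flies sits anywhere between the base threshold and the peak
contrast, a range of more than an order of magnitude. Raising the
threshold shrinks each fly to a dark core; cores are re-expanded by
assigning every original component pixel to the nearest core centroid
before refitting, which keeps sub-element areas on the area-model scale
(bare cores would be rejected as undersized). The first configuration
improving the likelihood product by >5 % wins; failed splits return the
original component — a merged blob is a legitimate detection that the
tracking layer resolves. Undersized components whose likelihood never
recovers are discarded as spurious.

## Plate and reflections

The plate is found on the background μ image by Canny edges + circle Hough
transform over radii 0.25–0.48 of the frame's short side, tie-broken by
accumulator vote then smaller radius, degrading to a disabled full-frame
ROI (with a logged warning) below a 0.4 normalized-vote floor — blank or
pathological frames never crash the pipeline. A configured `(cx, cy, r)`
override bypasses detection entirely. Detections whose ellipse lies
entirely within a boundary band (default 12 px) are masked as specular
reflections; artifacts that survive (e.g. with masking disabled) are
removed downstream by tracker probation.

## Tracking

State per fly: (x, y, Vx, Vy, θ, ω) in px, px/frame, rad, rad/frame, with
a constant-velocity transition and full-state measurement (H = I₆).
dt is one frame; fps only converts timestamps on output.

* **Q** (process) diag: position (0.5 px)², velocity (1 px/frame)², angle
  (0.1 rad)², angular velocity (0.1 rad/frame)². **R** (measurement) diag:
  position (0.5 px)², velocity (1 px/frame)², angle (0.1 rad)², angular
  velocity (0.2 rad/frame)². These are engineering defaults, exposed in
  config; R is a fixed prior rather than estimated from warmup residuals —
  on short clips the residual sample is small and a bad estimate
  destabilizes the gate, while the filter is insensitive to moderate
  misspecification. R is inflated ×100 whenever the assignment was
  non-unique, so predictions dominate through occlusions.
* **Velocity measurements** are weighted moving averages of finite
  differences (window 5, geometric decay 0.7, the newest difference
  up-weighted with the innovation magnitude, capped at ×3) — never the raw
  one-frame difference, which is noise-dominated at low resolution. The
  angular velocity comes from the same filter on the unwrapped orientation
  series.
* **Orientation** is an axis (mod π). Measurements are mapped to the
  representative nearest the predicted θ, so stored orientations never
  jump by more than π/2 and the filter sees a continuous angle.
* **Assignment**: Hungarian on −log of the Gaussian position score, square
  padding, gated at Mahalanobis 4 in the prediction's position marginal.
  The marginal's σ is floored at 2 px: a converged filter's formal σ
  (~0.7 px) would make the gate tighter than one body-length maneuver, and
  losing a fly over a sharp turn costs far more than an occasional wider
  gate. Exact ties are broken toward the lowest tracker id keeping its
  nearest detection.
* **Merges**: trackers left without their own detection join their best
  feasible detection's group. If the group's blob has single-fly size and
  cannot be split, it is *not* an occlusion — the best-scoring mature
  tracker keeps the detection (this is also how waiting trackers
  re-acquire). Real merged blobs are re-split at raised thresholds and the
  parts re-assigned within the group; failing that, an elongated blob
  (≥1.4·μ_areas) is split by k-means on its pixels seeded at the last
  known positions and refined by a Gaussian-mixture EM step, accepted only
  if the resulting centres separate by ≥4 px. Otherwise moving trackers
  coast on predictions; a static cluster (all speeds <0.5 px/frame) parks
  its trackers in `waiting` at their last known positions with the
  position spread widened to 20 px.
* **Lifecycle**: new trackers are provisional for a 50-frame probation (at
  15 fps); losing the blob, or joining a blob owned by another tracker,
  retires them immediately and their buffered rows never reach the output —
  this is what removes reflections and noise blobs. Trackers still inside
  probation when the sequence ends are likewise dropped. Mature trackers
  coast ≤15 frames, then wait ≤450 frames, then retire with a logged
  identity loss. Ids are never reused.

## Synthetic arena

Defaults mirror the reference imaging conditions: 480×480 px frames, a
180 px plate (4.5 cm at 4 px/mm), 8 flies (≈0.12 flies/cm²), 15 fps,
background level 220, fly peak contrast 120, additive Gaussian pixel noise
sd 3, fly half-axes (6, 3) px (≈3 mm at 4 px/mm). Flies are rendered as
anisotropic Gaussian darkening profiles with profile sd = half-axis/2,
because the segmentation models fly brightness as a 2-D Gaussian — this
makes the ellipse fit's targets analytic (recovered a = 2·sd). Motion is a
heading-persistent random walk (speeds 1–3 px/frame ≈ 4–11 mm/s, heading
noise 0.15 rad/frame) with specular wall reflection and no collision
dynamics: overlapping flies pass through each other, which is sufficient
to exercise merge/split logic.

Scripted events make interactions deterministic: `crossing_event` stages a
*transversal* crossing — the two approach bearings are forced at least 90°
apart via staging waypoints — because a trajectory crossing means the paths
intersect; two flies converging from the same side form a co-moving pair
whose correspondence is kinematically undecidable (that regime is exercised
separately by `stop_and_merge_event`, where disambiguation falls to the
waiting/k-means machinery). `reflection_event` plants a reduced-contrast
blob at the wall. A `min_separation` option adds soft mutual avoidance for
the non-interacting study condition. One RNG stream per dataset seed; frame
rendering derives a per-frame stream so frames are independently
reproducible, and regenerated datasets are byte-identical.

What the synthetic tests do **not** show: real flies have wings, legs,
grooming postures and contact dynamics; real backgrounds drift with
ambient light; real reflections correlate with fly pose. Passing tests
demonstrate the algorithmic contracts (estimator consistency, identity
conservation under the modeled conditions), not field performance on
recordings.

## Problem sizes in the test suite

Identity-conservation checks run on 500-frame, 480×480 px sequences (4
non-interacting flies; 8 flies with five scripted interaction events),
chosen to include several full interaction cycles while keeping the whole
suite under a minute of tracking time. Estimator-recovery checks use 500
noise frames (the scale at which the MAD's sampling spread is comfortably
inside the 10 % band) and 100 random blob poses.

## Known limitations

* No appearance model: after a failed occlusion (both flies stop, then
  part beyond the wait radius) identities can only be re-bound by
  position.
* Head/tail orientation is unresolved (axis mod π by construction).
* The error-frequency module treats occlusion *events* and occlusion
  *frames* as distinct inputs and never derives one from the other;
  published per-video event counts are not always recoverable from frame
  counts.
* Video containers are read through imageio only when a suitable plugin
  is present; numbered PNG/TIFF directories are the always-available path.
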