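# Methods

`ovigait` implements marker-based 3D gait analysis of the sheep (ovine)
hindlimb: from labeled marker trajectories to spatiotemporal gait
parameters, three-component joint angles, and angle-angle cyclograms.
Because no public sheep mocap recordings accompany the reference values the
package is built around, the package ships a forward-kinematic gait
generator whose output has exact, analytically known ground truth; every
stage of the pipeline is validated by recovering that truth.

## The measurement model

A trial is a `MarkerTrajectorySet`: labeled 3D points sampled at a fixed
rate (100 Hz for the capture protocol emulated here), in meters, lab frame
with Z up. Eleven anatomical landmarks are used per side: coxal tuberosity,
ischial tuberosity, greater trochanter, femoral shaft, femorotibiopatellar
joint (knee), tibial shaft, base of the calcaneus, IV metatarsal shaft,
metatarsophalangeal joint, distal phalanx, plus one distal forelimb marker
that only indicates ground contact. A `LandmarkMap` decouples marker labels
from anatomical roles.

### Gait events

Initial contact (IC) and toe-off (TO) are detected kinematically from the
distal hoof marker, without force plates. A frame is *stance* when

1. the marker's height is within `h_thresh` (default 15 mm) of the floor,
   estimated as the 2nd percentile of that marker's height in the trial, and
2. its horizontal speed is below `v_frac` (default 10 %) of its peak
   horizontal speed in the trial.

Speed is a **forward difference**: a frame is static if the hoof has not
moved by the next sample. This choice is deliberate — a centered difference
mixes the last stance frame with the first swing frame and systematically
delays TO by one frame. Using the horizontal speed *magnitude* makes
detection invariant to translating or yawing the lab frame, so no walking
direction is assumed. Contact runs are cleaned by filling interior gaps
shorter than `min_run` (default 3 frames) and dropping runs shorter than
the same window; this doubles as hysteresis and as the "merge nearby
events" rule. A contact run that touches the first or last frame of the
trial is partial and contributes no outer event (a whole-trial contact
degenerates to a single IC at the start).

On noise-free synthetic data whose contact boundaries fall on frames,
detection is frame-exact; when boundaries fall between frames (as at the
reference cycle time of 0.602 s) events are within one frame of truth.

### Cycles and quality control

Cycles are consecutive (IC, TO, next IC) triples per limb. QC mirrors the
exclusions a gait-lab operator applies (hesitation, dragging, running,
curved walking) with explicit thresholds, each rejection carrying exactly
one reason:

| check | default | reason |
|---|---|---|
| unfilled marker gap inside the cycle | any required marker | `marker_gap` |
| displacement speed of the reference marker | 0.5–2.0 m/s | `speed_out_of_range` |
| cycle heading vs. line of progression | ≤ 10° | `heading_deviation` |
| duty factor | 0.5–0.8 (walking) | `duty_factor_out_of_range` |

### Spatiotemporal parameters

The *line of progression* is a horizontal total-least-squares axis through
the hind contact points. Each side's contacts are centered before the fit:
this keeps an unbalanced left/right contact count from tilting the line and
places it midway between the two footfall tracks, which is what stride
width is measured against. Orientation follows the pelvis displacement.

Per cycle: stride length is the same-hoof IC-to-IC displacement projected
on the progression line; step length/time run from the contralateral IC to
the cycle's closing IC; stride width is the perpendicular separation of the
two limbs' contact points; double support sums all stance overlap of the
hind pair inside the cycle (both episodes — the reported "double limb
support time" is read this way); no-support is the span with neither hind
hoof down; speed = stride length / cycle time, so `speed × cycle_time =
stride_length` holds exactly, as do `stance + swing = cycle` and
`stance% + swing% = 100` (all three are constructed, not estimated).
Inter-limb timing uses the Abourachid lags: F (fore pair), H (hind pair)
and P (ipsilateral pair) delays as % of the reference limb's concurrent
cycle, modulo 100; a pair delay within 1 point of 0 is reported as 100,
the conventional value for a pace. Aggregation reports the mean and sample
(n−1) SD per limb and pooled; n = 1 groups report SD = 0 with n visible.

### Segment frames and joint angles

Five segments form the chain pelvis–thigh–shank–metatarsus–hoof. Each
segment's longitudinal axis Z runs along its two line landmarks (pelvis:
ischial → coxal tuberosity; thigh: greater trochanter → knee; shank: knee →
calcaneus; metatarsus: calcaneus → metatarsophalangeal; hoof:
metatarsophalangeal → distal phalanx). A two-marker segment leaves axial
rotation indeterminate, so a third, off-axis marker of the same limb fixes
the segment plane — the femoral and tibial shaft markers exist precisely
for this; the metatarsal-shaft marker serves the metatarsus and hoof, and
the greater trochanter serves the pelvis. Y is the plane normal (side-signed
so both sides share axis semantics), X = Y × Z. Axis semantics: X
medio-lateral (flexion/extension), Y anterior-posterior
(abduction/adduction), Z longitudinal (axial rotation). Frames are
validated orthonormal with det +1 to 1e−9 and rejected if construction
markers are within 1° of collinear (the error names the frame).

Joint rotation is `R = proximal^T · distal`, decomposed in the intrinsic
X–Y–Z Cardan sequence (closed form; β reported in (−90°, 90°), |β| > 85°
warns of gimbal proximity — walking gait stays far from it). Components are
unwrapped (no inter-sample jump > 180°). Reported signs: flexion/
dorsiflexion positive, adduction positive/abduction negative, external
rotation positive/internal negative; the left side flips the second and
third components so a symmetric gait reports identical curves for both
limbs. Processing a sagittally mirrored trial with the opposite-side model
preserves flexion and negates the non-sagittal components exactly (a tested
invariant). By default angles are *anatomical* (no static offset); a
standing trial can be supplied to subtract the standing posture instead
(`reference = static-offset`) — the large reference values at IC (≈ 45–47°
of knee flexion/ankle dorsiflexion) are only meaningful in the anatomical
convention.

Curves are linearly resampled to 101 points over [IC, next IC]; TO maps to
round(stance fraction × 100). Event summaries take IC = sample 0,
TO = that sample, stance extrema over samples [0, TO], swing extrema over
(TO, 100], aggregated as mean ± sample SD across cycles. Cyclograms pair
the flexion/extension components of two joints on the normalized grid
(other components selectable) and are quantified by shoelace area (deg²),
perimeter (deg) and progression orientation.

## The synthetic gait generator

The generator emulates the captured condition: overground lateral-sequence
walking (footfall order right hind → right fore → left hind → left fore,
phase offsets 0/0.25/0.5/0.75), 22 markers, 100 Hz. Defaults are the
reported means for healthy adult Merino ewes: cycle time 0.602 s, duty
factor 0.61, stride 0.695 m, stride width 0.191 m (fore 0.162 m), 1 mm
Gaussian marker noise; speed is derived (0.695/0.602 ≈ 1.154 m/s). Joint
angle profiles are **periodic monotone cubics (PCHIP on periodically
extended knots)** through anchors placed at the reported event values (IC,
stance extrema, TO, swing extrema); PCHIP passes through every anchor
exactly and cannot overshoot, so profile extrema *are* the anchor values.
Hip anchors carry all three components and the ankle its inversion/eversion
from the reported event table; the remaining non-sagittal components
default to small (≤ 5°) plausible amplitudes.

Construction is distal-first: the distal hoof marker follows an analytic
contact schedule — pinned to the floor for exactly the duty-factor fraction
of each cycle, advanced one stride per cycle during swing (cubic smoothstep
blended with a 20 % linear term, so lift-off and touch-down have nonzero
forward velocity, as real hooves do) with a squared-sine 8 cm clearance
arc. Segment orientations follow the prescribed Cardan profiles; marker
positions are chained proximally from the hoof anchor. Contact timing,
stride geometry, footfall phasing and every joint angle curve are therefore
known *exactly*, and the marker recipes invert the construction, so the
noise-free pipeline recovers frames to < 0.1° and curves to machine
precision. Steps are split 0.3745/0.3205 m (left/right), which preserves
the steady-gait identity step_left + step_right = stride.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real recordings: skin-motion artifact (markers
ride rigid segments here; in sheep, skin sliding at the stifle is the
dominant kinematic error source), cycle-to-cycle and inter-animal
variability (every cycle is identical up to noise, so recovered SDs reflect
noise, not biology), pelvis roll/pitch/yaw (the pelvis frame is
orientation-constant), asymmetries between left and right beyond the step
split, soft-tissue hoof deformation during stance, and a shared rigid
pelvis (each side's pelvis markers ride that side's hip, so the cross-side
pelvis distance breathes by a few millimeters). Both hindlimbs share one
cycle time; left/right differences in the reference tables are treated as
sampling variability.

## Numerical choices

- **Internal units**: meters, seconds, degrees; unit conversion only at the
  I/O boundary (C3D `POINT:UNITS`, TSV millimeters).
- **Gap filling**: cubic spline over time for interior runs ≤ 10 frames
  (0.1 s); longer and edge gaps stay flagged and invalidate their cycles.
- **Smoothing**: zero-phase (forward–backward) 4th-order Butterworth.
  The `lowpass_filter` default is the conventional 6 Hz for walking mocap,
  but the pipeline default is **10 Hz**: at 0.6 s cycles the swing transient
  carries meaningful energy above 6 Hz, and on synthetic reference gait a
  6 Hz cutoff biases ankle event angles by up to ~3°, while 10 Hz keeps all
  event angles within ~1° and still reduces 1 mm marker noise to ~0.4 mm.
  Event detection always runs on the *unfiltered* (gap-filled) trajectories,
  because the contact transient is exactly what the filter smears.
- **Ties and degenerate inputs**: first frame satisfying a condition wins;
  a static marker (zero peak speed) counts as contact by height alone;
  empty aggregations raise; a cycle wholly outside a series' span raises.
- **Determinism**: all randomness flows from the generator seed; re-running
  the pipeline on the same input yields byte-identical CSVs (tested).

## Problem sizes

Tests run on 10–20 synthetic cycles (≈ 700–1300 frames, 22 markers); the
acceptance script analyzes 85 cycles — the number of cycles the reference
aggregation is based on — in about a second. Recovery tolerances: ±0.01 m
lengths, ±0.01 s times, ±2 percentage points phase fractions, ±2° event
angles, ±0.03 m/s speed, at 1 mm noise.

## Known limitations

- The C3D codec covers labeled point data (float or scaled-integer, Intel
  byte order) plus the POINT parameter group; analog channels, event
  sections and DEC/MIPS byte orders are not read.
- Event detection assumes overground walking with a static stance hoof; it
  is not validated for treadmill data (belt-driven stance motion) or gaits
  with flight phases (running is deliberately rejected by QC).
- The hoof segment's axial orientation borrows the metatarsal-shaft marker
  and is only as good as that marker's placement; no hoof joint angle is
  reported.
- With only two pelvis markers per side, pelvis axial rotation about its
  own long axis is resolved by the greater trochanter, which sits on the
  femur; during large hip abduction this approximation degrades.
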