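# Methods

This note documents the models, defaults and design choices behind
`gazeassist`: what each stage assumes, which knobs matter, and what the
synthetic data can and cannot tell you about real recordings.

## Coordinate conventions and units

All computation is SI: positions in meters, forces in newtons, times in
seconds (gaze timestamps in milliseconds, mirroring vendor exports),
angles reported in degrees. The lab frame is y forward (anterior,
positive), z up, x lateral-right. Flexion, anterior tilt and dorsiflexion
are positive. Unit conversions (e.g. millimeter marker files) happen only
at the I/O boundary.

## Preprocessing

- **Synchronization.** Force-plate channels (1,000 Hz) are polyphase-
  resampled onto the marker clock (100 Hz, 10 ms spacing) with an
  anti-alias FIR; DC and sub-Nyquist sinusoids are preserved to <1%.
- **Smoothing.** Zero-phase (forward-backward) Butterworth low-pass,
  order 4: 6 Hz for marker coordinates, 18 Hz for forces. Order and phase
  behavior are conventions of the field rather than uniquely determined by
  the measurement chain, so both are config keys (`filter.order`,
  `filter.*_cutoff_hz`). Two-pass filtering squares the magnitude response
  and doubles the effective order; edge transients are handled by
  reflective padding of three filter lengths.
- **Gap interpolation.** Missing marker runs up to `gaps.max_gap_s`
  (default 0.2 s) are filled with cubic splines over up to five valid
  samples on each side; longer gaps are left missing and reported.
  Processing order is synchronize → ASIS reconstruction → gap-fill →
  smooth, so splines never fit filtered noise.

## Virtual ASIS reconstruction

During forward bending the anterior superior iliac spine markers are
occluded by the torso. A three-marker sacral jig defines an orthonormal
local frame; the jig→ASIS offset vectors are measured once on a static
standing capture (`static.csv` in each trial bundle) and re-applied every
frame, which is exact for a rigid pelvis. Where the real ASIS is visible,
the virtual-vs-measured discrepancy is reported as a quality metric.

## Whole-body COM and angles

The 10-segment model (trunk incl. head/neck, pelvis, L/R upper limb,
thigh, shank, foot) uses de Leva's (1996) adjusted Zatsiorsky mass
fractions with head+neck folded into the trunk and the arm segments
combined; fractions sum to 1 by construction and the table is swappable
(`anthropometry.table`) — e.g. for a population-specific table. Segment
COMs interpolate between proximal and distal landmark centroids; the
whole-body COM is their mass-weighted sum. Because the synthetic ground
truth is defined with the same table, recovery tests are insensitive to
the (unknowable) "true" fractions; on real data the choice of table
shifts absolute COM positions by centimeters and should be reported.

Trunk orientation comes from an orthonormal triad built on the jugular
notch, xiphoid, T2 and T7 markers; flexion is the x component of the
X-Y-Z Cardan decomposition relative to the lab. Ankle dorsiflexion is the
forward inclination of the shank axis (knee → lateral malleolus) over the
planted foot.

## Event detection

Seat-off is defined as the rear (chair) plates unloading to 0 N. A
literal zero never occurs with sensor noise, so the detector finds the
first epsilon-crossing (`events.seat_off_epsilon_n`, default 5 N)
sustained for a 50 ms debounce and returns the linearly interpolated
crossing; with ε = 0 on clean data this recovers the literal definition
exactly. A positive threshold biases the crossing early by ε/slope
(≈ 4–8 ms at typical unloading rates), which matters for the COM–BOS
index (≈ 3 mm at 0.45 m/s). The index pipeline therefore refines the
crossing by regressing the unloading ramp (10–60% of the seated load) and
extrapolating to 0 N — sub-millisecond accurate on piecewise-linear
unloading and unbiased under noise. Maximum ankle dorsiflexion is the
argmax of the smoothed dorsiflexion series in (seat-off, cycle end], ties
to the earliest sample; cycles are delimited midway between consecutive
seat-offs.

The trial-level value of each index is the mean over the five cycles.
Trial-level pooling (rather than participant means) is also the unit of
analysis for the kinematic t tests, giving df = n₁+n₂−2 = 118 at the
default cohort; this replicates the classical analysis but ignores
within-participant correlation — a mixed model would be the stricter
choice and is out of scope.

## Gaze analysis

Fixations: I-VT with `ivt.velocity_threshold_dps = 30` and
`ivt.min_fixation_ms = 60` (common vendor defaults; both exposed).
Inter-sample plane displacement is converted to visual angle at a nominal
1 m viewing distance. A fixation is a maximal run of below-threshold
steps between valid samples; its duration is sample count × sample
period. Invalid samples break runs.

AOIs live in a body-anchored 2D plane whose vertical coordinate is lab
height: head [chin, ∞), neck [acromion, chin), trunk [mid acromion–hip,
acromion), hip [mid-thigh, …), knee [mid-shank, mid-thigh), foot
(−∞, lateral malleolus). Bands are half-open [lower, upper): a point on a
shared boundary belongs to the upper band. The chin is not a marker; it
is estimated `aoi.chin_offset_m` (default 0.12 m) below the head-marker
centroid. A fixation's AOI is decided by its centroid at its midpoint
frame. This sidesteps the manual scene-video registration a wearable
tracker needs in practice: applying the package to real recordings
requires an external gaze-to-body-plane mapping step.

Metrics are computed over the support period — first stand-up onset
(trunk angular velocity exceeding 5 deg/s, or the scripted window when
present in trial metadata) to the hand-release time, which is metadata
because it is not observable from the collaborator's markers. AOIs never
fixated report a missing latency/visit value and are excluded listwise
from that metric's group means.

## Statistics

The mixed-design ANOVA uses the classical observation-weighted
sums-of-squares decomposition, valid for unbalanced group sizes, with the
standard error terms (subjects-within-groups for the between factor, its
within-subject interaction for the AOI factor); it matches pingouin's
implementation to machine precision. No sphericity correction is applied
by default because the design dfs (5, 110) are the uncorrected ones;
Greenhouse–Geisser is available via `correction="gg"`. Simple main
effects of experience at each AOI use the pooled error
(SS_subjects + SS_AOI×subjects)/(df_s + df_bs), whose expectation equals
the between-subject variance at a single AOI under compound symmetry;
Monte-Carlo calibration over 1,000 null cohorts puts its type-I error at
the nominal 5% within Monte-Carlo error. Bonferroni adjustment is
p_adj = min(1, m·p) with m = 15 AOI pairs.

## Synthetic data: what it emulates

The generator produces the study conditions as defaults: 7 expert and 17
novice participants, 5 consecutive stand/sit cycles per trial, 100 Hz
markers (34 body + 3 jig), 1,000 Hz forces on six plates (chair on the
two rear plates), 50 Hz gaze, group-conditioned distributions of deepest
trunk flexion (41.0 ± 2.1 / 37.8 ± 3.7 deg), COM velocity (0.436 ± 0.026 /
0.492 ± 0.067 m/s), COM–BOS distance (−0.023 ± 0.003 / −0.047 ± 0.032 m)
and per-AOI dwell/fixation-count profiles (head-biased for experts,
diffuse for novices).

- **Motion model.** A planar (sagittal) articulated chain driven by
  piecewise minimum-jerk joint profiles: forward lean to the scripted
  peak flexion (held briefly through seat-off), extension with a
  unimodal dorsiflexion peak, a stand phase, and a shallower reverse
  lean for sit-down. Lateral coordinates stay near-constant. All
  reported indices are sagittal, so nothing is lost by planarity.
- **Exact index realization.** The rear-plate force is piecewise linear
  and reaches 0 N exactly at the scripted seat-off. Over a ±0.1 s padded
  window around [seat-off, max dorsiflexion] the whole-body COM is made
  exactly linear — passing through heel_y + COM-BOS at seat-off with
  slope equal to the scripted velocity — by a smooth forward shift of
  every segment above the knee. The shift is a pure translation, so trunk
  and ankle angles and the heel line are untouched, and because the COM
  is linear across the whole padded window, small event-detection errors
  do not bias the recovered velocity.
- **Variance structure.** 70% of each group variance lies between
  participants, 30% within (configurable); only pooled spreads are
  reported, so the split is a modelling choice. Nonnegative gaze
  quantities use moment-matched gamma distributions (a clipped normal
  would inflate small means such as the novice head dwell by ~25%); the
  dwell and count of an AOI share one quantile, so heavy looking and
  frequent fixating co-occur, as they do empirically. Kinematic indices
  use normals.
- **Noise and dropout.** Marker noise 0.5 mm (typical optical capture),
  force noise 2 N, within-fixation gaze jitter 0.5 mm; the ASIS markers
  are blanked whenever trunk flexion exceeds 25°, forcing the virtual-
  marker machinery into every deep-lean trial.
- **Anthropometrics.** The collaborators' mass/stature are not reported
  anywhere authoritative; defaults are 60 kg / 1.65 m with the chair at
  0.415 m, all exposed in `CohortConfig`.
- **Seeding.** One master seed is split hierarchically per participant /
  trial / stream, so adding a participant leaves everyone else's data
  byte-identical.

**What passing tests do not show.** The generator has no soft tissue
artifact, no marker relabeling errors, no camera dropout beyond the ASIS
occlusion, no gaze-estimation drift or parallax, no scene-video
registration error, and fixation episodes are ideal low-velocity
clusters. Recovery of the configured distributions therefore validates
the pipeline's correctness, not its robustness to every real-world
artifact.

## Problem sizes

Default verification runs use the full study-sized cohorts (7×5 and 17×5
trials, ≈ 40 s per trial at native rates), 1,000 random streams for the
I-VT oracle comparison and 1,000 simulated metric tables for the null
calibration of the simple main effect — sizes chosen so the whole suite
completes in about a minute on a single core while keeping Monte-Carlo
error well below the tolerances being checked.

## Known limitations

- Real-data gaze must be mapped into the body plane externally; only the
  canonical bundle and C3D marker/force ingestion are provided.
- Trial indices assume five clean cycles; trials with missed seat-off
  events fail loudly rather than imputing.
- The simple-main-effect error term assumes compound symmetry; with
  strongly heterogeneous AOI covariances, per-level one-way tests would
  be safer.
- The t tests on pooled trials inherit the classical analysis's
  independence assumption across trials of one participant.
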