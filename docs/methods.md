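# Methods

## Coordinate conventions and calibration

Pose tables arrive in one of two dialects. The markerless dialect is a
CSV with three header rows (scorer / bodyparts / coords) and an
x, y, likelihood triplet per body part, in pixels, image-oriented
(y grows downward). The reference dialect is a long-format metric table
(`frame, marker, x_cm, y_cm`), already in the anatomical frame, plus a
joint-angle table and an alternating contact/liftoff event list. Frame
indices are 0-based and contiguous; event files using 1-based indices are
converted at ingestion (`events_one_based`).

Pixel tracks are converted to cm with a scale derived from two static
calibration markers a known 10 cm apart: `cm_per_px = 10 / mean pixel
distance`, the mean taken over all frames because the markers are
physically static and averaging suppresses tracking jitter. All geometry
downstream assumes the anatomical frame (y up, x rostral); `orient`
negates y and, when the animal faces the −x image direction, x. Both
operations are isometries, so distances and angles are unaffected; only
signed x-based quantities (toe–hip distance) require the convention.

Sub-threshold markerless points (default likelihood < 0.9) are replaced
by linear interpolation between the nearest confident frames, with edge
gaps held constant; the per-marker replacement count is reported. The
threshold and the fill itself are deliberately exposed configuration, not
silent behaviour, because confidence filtering policies differ between
laboratories.

## Events, cycles and the 12 variables

A cycle runs from one paw contact of the analyzed (right) hindlimb to the
next; liftoff is the frame of the toe's most caudal position and splits
the cycle into stance and swing. Durations are exact frame arithmetic, so
summed cycle durations telescope to (last contact − first contact)/rate.
Events are normally imported from manual annotation. The optional
detector operationalises the definitions: liftoffs are caudal extrema of
toe x (earliest frame on ties, matching the "first frame" convention used
for contact), contacts are the first frame after the swing apex at which
toe height re-enters a band above the stance baseline (default 10% of the
vertical toe excursion); candidate cycles shorter than 0.2 s are
suppressed. These two thresholds are artifact decisions — the underlying
definition of "visible contact" is perceptual — and are exposed in the
trial configuration.

Per cycle, the package computes step length (|x| separation of the two
hindpaw toes at right contact; horizontal because at contact both paws
are on the belt plane and the other length variables are horizontal),
stride length (stance toe displacement + swing duration × belt speed,
in cm), signed toe–hip horizontal distances at contact and liftoff
(positive = toe rostral of the greater-trochanter marker), and the
included angle at hip (crest–hip–knee), knee (hip–knee–ankle), ankle
(knee–ankle–MTP) and MTP (ankle–MTP–toe) at contact and liftoff, in
degrees, computed from the segment vectors (equivalently the law of
cosines). The knee can be a tracked marker or, in reference-tracker
parity mode, extrapolated as the circle–circle intersection at femur and
shank distance from hip and ankle, taking the anterior solution (the
cat's knee points forward); segment lengths default to per-trial medians
of the tracked distances.

Angle traces are resampled per cycle onto 256 bins by linear
interpolation, bin 0 anchored at the contact frame and the next cycle's
contact excluded (half-open cycles, so consecutive cycles never share a
frame); across-cycle mean and SD are bin-wise, sample (n−1) SD, with SD
defined as 0 for a single cycle.

## Agreement statistics

Paired per-cycle series (same cycles, two methods) are summarised with:

* **QQ triage.** Sorted sample values against fitted normal quantiles
  μ̂ + σ̂·Φ⁻¹((i−0.5)/n), with μ̂, σ̂ from the least-squares
  probability-plot fit — the one estimator for which a sample that *is*
  a set of exact normal quantiles lies on y = x identically. The
  correlation of the point cloud (probability-plot correlation
  coefficient) is reported as a linearity score; the automated verdict
  (score ≥ 0.995) is only a logged suggestion, since the original
  workflow this mirrors judged QQ plots visually. Pipelines should pass
  explicit per-variable verdicts.
* **ICC(A,1)** for normal variables: two-way ANOVA with cycles as
  subjects and methods as raters,
  ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), CI by the
  McGraw–Wong F interval. Undefined (error) when all values are
  identical.
* **Lin's CCC** otherwise: 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²) with 1/n
  moments (the 1989 convention; the n−1 discrepancy is O(1/n)), CI via
  the Fisher-z asymptotic variance. `ccc_from_summary` evaluates the
  equivalent closed form from published means/SDs/r, which is how the
  two desk-scale reproduction targets are computed.
* **Pearson's r** and **Bland–Altman** limits (diff = reference − test,
  limits = mean ± 1.96 × sample SD) always.
* **Interpretation scales** with inclusive lower bounds and a closed top
  class: ICC < 0.5 poor / 0.75 / 0.9 excellent; CCC < 0.90 poor / 0.95 /
  0.99 almost perfect; |r| graded negligible → very strong at
  0.10/0.40/0.70/0.90. The r scale classifies the magnitude.

CCC ≤ |r| always, with equality iff the two methods share mean and
variance; this and the swap symmetries (ICC/CCC invariant, Bland–Altman
bias sign-flips) are property-tested.

## The synthetic generators

**Measurement model.** x = t + β_A + ε_A, y = t + β_B + ε_B with latent
t ~ N(μ, σ_t²). Its population concordance,
CCC = 2σ_t²/(2σ_t² + σ_A² + σ_B² + Δβ²), provides closed-form targets
for estimator-recovery tests (e.g. σ_t² = 25, σ_A = σ_B = 1, Δβ = 0 gives
50/52 ≈ 0.9615).

**Trajectory model.** A planar chain crest→hip→knee→ankle→MTP→toe at
60 Hz. The treadmill frame is the world frame: during stance the toe is
carried caudally at belt speed through a roughly speed-invariant sweep
(default 23.5 cm), so stance duration = sweep/belt speed, while swing
lasts ~0.3 s — at 0.4 m/s this yields ~0.9 s cycles at ~65% duty, and
faster belts shorten stance, as observed in cats. Swing returns the toe
to the next landing spot along a smoothstep path with a sinusoidal
3 cm arc, making liftoff the unique caudal x extremum by construction.
The hip translates only vertically (0.5 cm oscillation about 25.3 cm);
foot pitch and the MTP→ankle segment follow single-sinusoid templates
phased so the paw is flat at contact and heel-up at liftoff; the knee is
placed by the same circle–circle intersection the analysis uses, so
tracked and extrapolated knee modes coincide exactly on noiseless data.
Segment lengths (femur 13.2, shank 14.8, tarsus 6.5, foot 3 cm) are in
the range of a 3.5–4.5 kg cat and leave ~1 cm of reach margin at the
most extended pose encountered across speeds 0.4–1.0 m/s.

The animal's own cycle-to-cycle variability — shared by both tracker
renderings — comes from seeded per-cycle draws: timing CV 6%, landing
position SD 1.0 cm, swing height CV 10%, template amplitude CV 8% and
posture offsets of 0.04 rad. Spatial draws are truncated at ±2 SD because
the limb cannot overstride its own reach. These values were chosen so
that biological variance dominates sub-pixel tracker noise, the premise
of a method-comparison study (with ~0.05 cm jitter the length variables
then sit above ICC 0.99); they are deliberately larger than zero but far
smaller than the pooled-across-speeds SDs a multi-trial study reports.

**Renderings.** The markerless-style rendering converts cm to pixels
(0.1 cm/px, image y-down, 640×480-scale geometry), appends the two
static calibration markers, adds i.i.d. Gaussian jitter (default 0.5 px),
and simulates confidence as Beta(40, 1) with 2% dropouts (confidence
~U[0, 0.5] plus a 20 px position outlier). A fully noiseless rendering
reports confidence exactly 1.0 — a zero-noise tracker has nothing to be
uncertain about — so the noiseless limit is exactly invertible through
calibration and orientation. The reference-style rendering adds static
per-marker placement offsets (default SD 0.1 cm, emulating reflective-
marker placement variability) plus 0.05 cm jitter.

What the generator does *not* emulate: skin movement over joints
(systematic, gait-phase-correlated marker error), paw dragging after
injury, occlusions longer than single-frame dropouts, out-of-plane (3D)
motion, and inter-animal variation. Passing tests on synthetic data
therefore demonstrate correctness of the measurement and statistical
machinery under the stated error model, not field performance of any
tracker.

## Numerical choices and limitations

* Angles are computed in radians and reported in degrees; arccos inputs
  are clipped to [−1, 1].
* The 256-bin grid spans the cycle's own frames, bins equally spaced from
  the contact frame to the last pre-contact frame.
* Knee extrapolation at the collinear boundary (d = femur + shank)
  returns the on-segment point; beyond it, an error.
* ICC/CCC confidence intervals collapse to a point at perfect agreement
  rather than produce NaNs from the degenerate F/z formulas.
* Report CSVs are written with 17 significant digits so that reruns are
  checksum-identical.
* Joint-angle template means reproduce the reported cat ranges to within
  roughly 15°; the ankle runs somewhat more dorsiflexed than published
  means. Only plausibility and periodicity matter for the tests, since
  every expected value is taken from the generator itself, but users
  fitting real data should not read the default templates as a
  biomechanical model.
* Small-segment angles (MTP, 3 cm lever) amplify coordinate noise ~19×
  more per cm than the length variables; at realistic jitter their
  agreement is genuinely lower. This is a property of the measurement
  geometry, not an artifact of the implementation.
* Default problem sizes (15 cycles/trial for trajectory work, n = 2500
  for measurement-model recovery) keep every check well-resolved while
  the whole suite runs in seconds.
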