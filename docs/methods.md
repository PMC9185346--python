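# Methods

## Coordinate and data conventions

Keypoints follow the COCO-17 layout in estimator output order, in pixel
coordinates with the origin at the top-left image corner and y increasing
downward, 0-based frame indices.  All reported metrics are signless, so
the y-axis direction never affects a result; it matters only for the raw
(unreported) sign of absolute angles.  Coordinates are never rounded,
flipped or clipped on input or output.

`image_id` strings in estimator result files are mapped to frame indices
via the numeric part of the filename stem (estimators emit image
filenames), falling back to natural-sort rank for non-numeric stems.
Multi-person recordings are resolved by tracker identity (`idx`), with
"auto" selecting the track covering the most frames (tie: highest mean
detection score); duplicate detections of one track in one frame keep the
higher-scoring one.

## Cleaning

A frame is excluded iff a required keypoint's confidence falls below
`min_keypoint_confidence`, or the fraction of all 17 keypoints at or above
that threshold falls below `min_fraction_valid`.  Defaults: threshold 0.3,
required = the four torso anchors (both shoulders and hips — the landmarks
every scaling rule needs), minimum valid fraction 0.5.  These defaults are
this package's choices; the source clinical protocol excluded
occluded/lost frames manually and published no thresholds.  The filter is
idempotent and monotone in the threshold.

Likelihood (confidence) summaries average per *unit*; the default unit is
one segment (mean over frames × 17 keypoints), with segments-pooled-per-
participant-and-direction available as an alternative since the original
summary unit is not published.  The grand SD uses the n−1 denominator, as
do all variances in the package (a single global `ddof` switch exists on
the distance-variance functions for sensitivity checks).

## Normalization

Per-frame reference extents (w_i, h_i) are computed from the original,
unshifted coordinates; every scaling rule is translation-invariant, so
this equals the shifted computation and is fixed for determinism.  The
segment means (w0, h0) average over the frames retained after cleaning,
within one segment only — never pooled across segments, because the
reference is meant to track that segment's own average apparent size.

Numerical choices:

* **Epsilon guard** 1e−6 px on w_i and h_i.  Anything smaller is below
  pixel quantization; the S (shoulder-box) and H (hip-box) rules provably
  collapse in frontal walking whenever the shoulder or hip landmarks are
  level, which is the geometric reason those methods are fragile.
* **Degenerate-frame policy**: `error` (default) raises with the method
  and frame index; `skip` drops the frame from both the reference mean and
  the output, with a warning.
* Outputs are not clipped to the 1280 × 720 frame: clipping would corrupt
  distances.  The recentering offset defaults to (640, 200) — suitable for
  1280 × 720 footage — and is configurable because it is resolution-
  specific.

Exact guarantees (all covered by tests): the output mid-shoulder point is
(x0, y0) in every frame; the method's own extent equals (w0, h0) in every
output frame; normalization is idempotent; isotropic methods change no
relative or absolute angle.

One subtlety: normalization is *not* invariant under arbitrary per-frame
similarity warps of the input, because (w0, h0) deliberately keeps the
segment's mean pixel size — a globally ×2 larger input yields a ×2 larger
output.  The exact statements are: a per-frame warp changes the output
only by the global per-axis factor (w0′/w0, h0′/h0) about the offset, and
a warp that preserves the mean reference scale changes nothing.  The test
suite asserts both forms.

## Evaluation

Relative angles (elbows: wrist→elbow vs elbow→shoulder; knees: hip→knee
vs knee→ankle) lie in [0, 180]; absolute angles (the same eight limb
vectors against the horizontal axis) are undirected, in [0, 180).  Angle
errors are minimal circular differences — wrapped into [0, 90] for
absolute angles, so 179° vs 1° is a 2° error — preventing spurious
wrap-around errors.  Aggregation order is mean over frames → mean over
segments → mean over the angle set; the order is recorded in the report
metadata because alternative orders differ only at second order.

Distance variance uses the per-segment sample variance (ddof = 1) of the
per-frame Euclidean distance of a bilateral pair, averaged across
segments, optionally within one group.  The Mann–Whitney U statistic is
the rank-sum form for the first sample with midranks for ties; p values
are exact by enumeration for tie-free samples with n ≤ 12 and otherwise
use the normal approximation with tie and continuity corrections (both
routes are delegated to scipy; an independent brute-force enumeration
oracle lives in the test suite).  The sampling unit for group tests is the
segment.  No multiple-comparison correction is applied by default; a Holm
step-down option exists.

## Synthetic generator

The generator states a world and keeps it fixed:

* **Body**: rigid torso (shoulder width 2.0, hip width 1.4, trunk 3.0,
  upper/lower arm 1.4/1.3, thigh/shank 1.8/1.7 canonical units; 26
  px/unit, i.e. a body of roughly 180 px at camera scale 1), static head
  landmarks, limbs swinging sinusoidally in the coronal plane (arms 15°,
  legs 10° base amplitude, 1 Hz stride at 25 fps).
* **Camera**: weak perspective — a per-frame uniform scale following a
  linear ramp (1 → 2 by default; reversed for walking away), handheld
  translation jitter (SD 3 px), additive Gaussian keypoint noise (SD
  1 px), Gaussian confidences (mean 0.89, SD 0.05, clipped to [0, 1]) and
  Bernoulli keypoint dropout (rate 0.02, confidence forced to 0).  The
  confidence level matches what a modern pose estimator attains on clinical
  footage after cleaning.
* **Profiles**: limb-swing variability is the only group difference.
  Cycle-to-cycle amplitude CV / within-cycle angle jitter SD:
  CON 0.07 / 0.5°, DCD 0.15 / 1.5°, EOA 0.40 / 4.0°.  Both mechanisms are
  forms of the increased limb-placement variability that characterizes
  ataxic gait; the within-cycle term (dysmetria-like irregularity) makes
  the EOA > CON wrist/ankle-variance ordering hold by construction rather
  than as a marginal sampling effect.  Mean amplitudes are identical
  across groups.

Randomness: each random quantity (cycle amplitudes, limb jitter, camera
jitter, keypoint noise, confidences, dropout) has its own labelled
substream derived from the seed and is drawn as a single frame-major
array, so runs are bit-reproducible and extending `n_frames` never
reshuffles earlier frames.

What the generator does **not** emulate: out-of-plane rotation of the
trunk, true pinhole perspective (foreshortening gradients across the
body), pose-estimator bias structure (e.g. systematically misplaced
ankles), occlusion geometry, or temporal correlation in keypoint noise.
A green test therefore establishes that the implementation removes
exactly the variability class it claims to remove — not that the method
is robust to model classes the normalization was never designed for.

## Pipeline and reproduction

`run_pipeline` is deterministic given its config and seed; the report
embeds the full configuration, per-stage frame counts and all decision
settings.  `reproduce_study` recomputes the headline statistics
(likelihood before/after cleaning with a paired t test, per-method angle
errors and distance-variance tables) from a directory of estimator result
files; it runs end-to-end on synthetic estimator files in the tests, and
on the study's deposited skeleton data when that is available locally.

## Known limitations

* The S and H scaling rules degenerate on level shoulders/hips; the skip
  policy trades frames for robustness but changes the reference mean.
* Exact Mann–Whitney p values are only available tie-free; per-segment
  variances are continuous, so ties are practically impossible there.
* No temporal smoothing and no pixel-to-meter calibration are attempted;
  all distances are in pixels of the normalized frame.
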