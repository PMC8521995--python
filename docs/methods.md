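# Methods

## The measurement model

The input is a time series of 17 named 2-D keypoints (COCO layout) with
per-keypoint confidences, as emitted by a browser-side pose estimator for a
person facing the camera. Image coordinates are used as-is (y grows
downward); every quantity that enters a score is a ratio of distances, so
scores are invariant under scaling and translation of the image frame —
camera distance and framing do not matter. This invariance is asserted by
property tests.

Three per-frame signals feed the rubric:

* shoulder and knee widths as **horizontal (x) separations**, not Euclidean
  distances. For a camera-facing squatter the x-separation is the stable
  stance measure and is insensitive to the slight forward crouch of a squat;
* **hip elevation** = mean knee y − mean hip y, the signed height of the hip
  midpoint above the knee midpoint. This is the reference that makes the
  depth score's sign work: a full squat carries the hip *below* the knee, so
  the normalised hip height goes negative (the −10% worked example), exactly
  matching the partial / parallel / full depth taxonomy. Left and right
  hip/knee y-coordinates are averaged before the difference is taken.

The standing baseline `Height_hip(0)` is the **median hip elevation over the
first 0.5 s** rather than literally frame 0, to be robust to first-frame
detection jitter. If the recording starts mid-descent the baseline is biased
low by up to ~2%; with any standing lead-in (which the pacing voice
enforces in deployment) it is unbiased. A non-positive baseline (hip at or
below the knee while "standing") raises a degenerate-posture error.

## Cleaning

Keypoints below `min_confidence = 0.2` make a sample undefined. Undefined
gaps up to `max_gap = 0.5 s` are bridged by linear interpolation; a longer
gap raises an unusable-sequence error rather than inventing motion. Signals
are then resampled onto a uniform grid at the sequence's nominal frame rate
(timestamps are authoritative; the nominal rate only sets the grid), and a
centred moving average of `smoothing_window = 0.2 s` removes residual
estimator jitter. Smoothing is applied on the uniform grid (after
resampling) so the window has a fixed sample count; for near-uniform input
this is equivalent to smoothing first. The 0.2-s window attenuates the 6-s
squat fundamental by < 0.2%, so band decisions are unaffected.

## Segmentation

Rounds are cut by a fixed clock — `n_rounds = 10` half-open windows of
`round_duration = 6 s` — mirroring the deployed voice-paced protocol; the
rhythm score presumes the 6-s clock, so adaptive repetition detection would
change the measurand. Every sample in the 60-s set belongs to exactly one
window (asserted exhaustively); a set short of samples is scored with
trailing empty rounds and a warning, and anything shorter than one round is
an error.

For recorded files with no pacing cue, `detect_start` places the clock
origin: the first hip descent is found (hip height falling below
100 − threshold %, default threshold 10%), the depth of that repetition is
read from the following 3 s, and the origin is set **1.5 s (a quarter round,
half the descent) before the half-depth crossing**. For a cosine descent the
half-depth crossing occurs exactly mid-descent, so the estimate is exact on
clean input and recovers a simulated 2-s offset to within one frame.

## Scoring choices

* **Band boundaries** follow the printed inequality directions exactly:
  knee-width bands are lower-closed/upper-open, depth bands upper-closed,
  rhythm bands lower-closed.
* **Knee-width mode ties** break toward the lower score: ambiguity never
  inflates performance.
* **Rhythm normalisation** uses the round's own min/max. The trace therefore
  always touches ±1; a motionless round (max = min) is degenerate and scores
  0 rather than dividing by zero.
* **The ±30% optimal-rhythm band** is additive in the normalised [−1, 1]
  units (±0.3 around `cos(πt/3)`), i.e. 30% of the half-range — a constant-
  width band. A band proportional to the curve's instantaneous value would
  vanish at the zero crossings and make the score discontinuous there.
* **Undefined samples** are excluded from both the knee-width mode and the
  rhythm counts (`N_rhythm`, `N_all`); a round with fewer than 50% defined
  samples is flagged `low_quality` in the diagnostics but still scored.
* The **volume law** is linear through the origin, fixed by the 8 → 80/20
  anchor and the qualitative rule that better rounds play clearer music;
  BGM% + noise% = 100 is an invariant.

## The simulator

`simulate_squat` emulates what a pose estimator returns for a camera-facing
squatter in a ~640×480 frame: the hip midpoint follows
`baseline · [(1+d)/2 + (1−d)/2 · cos(πt'/3)]`, so the normalised hip height
sweeps 100% → 100·d% → 100% each round; knee and shoulder x-separations are
fixed by the stance ratio; the other 13 keypoints ride a simple articulated
template (rigid torso of 110 px, arms held parallel to the ground, head
above the shoulders, knees fixed at 370 px). The cosine trajectory makes the
ideal profile sit exactly on the optimal rhythm curve, so the maximum-score
case is analytic rather than tuned.

Defaults model the deployed protocol and a realistic webcam geometry:
30 fps, 10 rounds of 6 s, 100-px shoulder width, 120-px standing
hip-over-knee distance, depth −0.1 (just below parallel), stance ratio 1.10,
confidence 0.9. Presets degrade one dimension each: `shallow` (depth 0.6),
`narrow`/`wide` (stance 0.9 / 1.8), `rushed` (3-s cadence against the 6-s
clock — analytically ~22% of samples in band, hence 1 rhythm point), `noisy`
(2 px i.i.d. Gaussian jitter, small against the 120-px hip excursion).
Jitter is drawn from a seeded generator; equal profiles give byte-identical
serialised output.

What the simulator does **not** model: correlated tracking error, occlusion
and identity swaps, knee-bend trajectories (knee y is fixed), perspective
and lens distortion, or intra-person variability. Passing tests therefore
demonstrate the correctness of the scoring logic under the stated protocol,
not robustness to real pose-estimator failure modes.

## Cohort rules

Age groups are younger ≤ 39, middle 40–59, older ≥ 60 (resolved from the
published group ranges). Monthly activity minutes are the product of
category midpoints — sessions/month {over 5/wk: 20, 3–4/wk: 14, 1–2/wk: 6,
1–2/mo: 1.5} × minutes/session {over 60: 60, 30–50: 40, 10–20: 15, < 5: 5};
the mapping is monotone in both arguments and configurable. The habit
dichotomy puts exactly 240 min/month in the *regular* class so the two
classes are exhaustive. Percentages are rounded half-up to one decimal, the
convention that reproduces the published table percentages from their
counts.

## Problem sizes and numerics

The test suite and the acceptance script run on simulated 60-s sets at
30 fps (1 801 samples, 180 per round) plus randomised property suites of
1 000 rounds — desk-scale inputs chosen to match the deployed protocol; the
whole suite runs in a few seconds. Timestamp grids are generated as
`t0 + k/fps` so spacing is uniform to 1e-9 s; window membership uses
half-open interval searchsorted semantics; float serialisation uses `repr`
so file round-trips are exact.

## Known limitations

* Frontal view only; sagittal (side-view) depth and back-angle analysis is
  out of scope.
* Fixed-cadence segmentation cannot count self-paced repetitions.
* The knee-width score uses horizontal separations, which conflates stance
  width with knee valgus when the camera is off-axis.
* Survey habit classification depends on the category-midpoint convention;
  raw per-respondent minutes are not observable from the categorical answers.
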