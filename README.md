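# squatscore

Rule-based evaluation of body-weight squats from 2-D pose keypoints, with
score-driven audio feedback — the analysis engine behind browser-based
home-fitness coaching.

A camera-facing exerciser performs a paced set of 10 squat repetitions, one
repetition every 6 s ("sit back" in 3 s, lift up in 3 s; 60 s per set). A
pose estimator (PoseNet-style, COCO 17-keypoint layout) turns the video into
per-frame keypoint coordinates; `squatscore` consumes those trajectories and
scores each repetition on three indices:

* **Index 1 — knee width (0–3 points).** The stance signal is the
  knee/shoulder horizontal-width ratio,
  `Index1 = Width_knee / Width_shoulder × 100%`, banded per sample
  (3 points for 100 ≤ r < 125%, 2 for 125 ≤ r < 150%, 1 for 150 ≤ r < 175%,
  0 otherwise); the round score is the most frequent per-sample band.
* **Index 2 — hip position (0–3 points).** The depth signal is the hip
  height above the knee, normalised by its standing baseline,
  `Index2 = min(Height_hip(t) / Height_hip(0) × 100%)`: ≤ 0% (a full,
  below-parallel squat) scores 3, (0, 25]% scores 2, (25, 50]% scores 1,
  shallower scores 0.
* **Index 3 — rhythm (0–4 points).** Within each round the hip trajectory is
  rescaled to [−1, 1], `Rhythm(t) = 2·(H(t) − H_min)/(H_max − H_min) − 1`,
  and compared against the optimal cadence `Optimal(t) = cos(πt/3)`. The
  fraction of samples within ±0.3 of the optimal curve is banded: ≥ 80% → 4,
  [60, 80)% → 3, [40, 60)% → 2, [20, 40)% → 1, < 20% → 0.

A round totals 0–10 points, a set 0–100. The audio feedback plays background
music against masking noise with volumes linear in the round total: a round
scoring 8/10 plays BGM at 80% of maximum and noise at 20%, so the two always
sum to 100%.

The package also ships a seeded squat-kinematics **simulator** (so the whole
pipeline is testable without video), and a **cohort** module implementing the
survey-side rules: age groups (younger ≤ 39 y, middle 40–59 y, older ≥ 60 y),
monthly physical-activity minutes from frequency/duration categories, and the
240 min/month regular-vs-insufficient exercise-habit dichotomy.

## Worked example

```python
from squatscore import derive_series, preset, score_set, simulate_squat, volume_envelope

seq = simulate_squat(preset("ideal"))      # 60 s of pose frames at 30 fps
series = derive_series(seq)                # widths, ratios, normalised hip height
ss = score_set(series)                     # 10 fixed 6-s rounds, scored
print(ss.grand_total, ss.sum_index1, ss.sum_index2, ss.sum_index3)
print(volume_envelope(ss).rounds[0])
```

prints

```
100 30 30 40
RoundVolume(round_index=1, bgm_pct=100.0, noise_pct=0.0)
```

— the ideal profile (knees 10% wider than shoulders, hip descending to −10%
of its standing height on an exact 6-s cosine) earns the maximum 10 points
every round, so the set totals 100 and the music plays clean at full volume.
Degraded presets isolate one fault each, e.g.

```
shallow  set total  70/100  (round 1: knee=3 hip=0 rhythm=4)
wide     set total  70/100  (round 1: knee=0 hip=3 rhythm=4)
rushed   set total  70/100  (round 1: knee=3 hip=3 rhythm=1)
```

(`examples/01_simulate_and_score.py`; see `examples/` for the volume
envelope and cohort summaries).

## Command line

```bash
squatscore simulate --preset ideal --seed 7 --out set.json
squatscore score --input set.json --out report.json
squatscore cohort --input survey.csv --out-json summary.json
squatscore validate --input set.json
```

`score` writes a JSON report (per-round indices and totals, set sums, volume
envelope; schema in `src/squatscore/schemas/`). Logs go to stderr, results
to files/stdout, exit codes are stable per error class.

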