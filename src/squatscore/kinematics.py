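"""Derive the scalar signals the scoring rubric consumes.

From a camera-facing pose trajectory we extract, per frame:

* ``width_shoulder`` — horizontal (x-axis) separation of the shoulders, px.
* ``width_knee`` — horizontal separation of the knees, px.
* ``knee_ratio`` — ``width_knee / width_shoulder × 100`` (%), the stance
  quality signal.
* ``hip_elev`` — signed vertical distance of the hip midpoint ABOVE the
  knee midpoint, px.  Positive while standing, zero at parallel depth,
  negative below parallel.  (Image y grows downward, so this is
  ``mean(knee y) − mean(hip y)``.)
* ``hip_norm`` — ``hip_elev / hip_elev(baseline) × 100`` (%), the depth
  signal: 100 standing, ≤ 0 at/below parallel.

Widths are x-separations rather than Euclidean distances because the
exerciser faces the camera and x-separation is robust to slight crouching.
The standing baseline is the median hip elevation over the first 0.5 s,
which is robust to first-frame detection jitter.

Cleaning: keypoints below a confidence threshold become undefined samples,
gaps up to ``max_gap`` seconds are linearly interpolated, signals are
resampled onto a uniform grid at the sequence's nominal frame rate, and a
short moving average removes residual estimator jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DegeneratePostureError, UnusableSequenceError
from .keypoints_io import PoseFrame, PoseSequence


@dataclass(frozen=True)
class CleaningConfig:
    """Signal-cleaning parameters.

    min_confidence: keypoints below this confidence are treated as missing.
    smoothing_window: moving-average length in seconds (0 disables).
    max_gap: longest low-confidence gap (seconds) bridged by linear
        interpolation; a longer gap makes the sequence unusable.
    """

    min_confidence: float = 0.2
    smoothing_window: float = 0.2
    max_gap: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_confidence < 1.0):
            raise ValueError("min_confidence must be in [0, 1)")
        if self.smoothing_window < 0:
            raise ValueError("smoothing_window must be >= 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


DEFAULT_CLEANING = CleaningConfig()

#: Seconds of the opening of the set over which the standing baseline is taken.
BASELINE_WINDOW_S = 0.5


@dataclass
class KinematicSeries:
    """Uniformly sampled per-frame signals derived from a pose sequence."""

    t: np.ndarray
    width_shoulder: np.ndarray
    width_knee: np.ndarray
    knee_ratio: np.ndarray
    hip_elev: np.ndarray
    hip_norm: np.ndarray
    baseline_hip: float
    fps: float

    def __len__(self) -> int:
        return len(self.t)


def _pair_x_separation(frame: PoseFrame, left: str, right: str, min_confidence: float) -> float:
    lk, rk = frame[left], frame[right]
    if lk.confidence < min_confidence or rk.confidence < min_confidence:
        return math.nan
    return abs(lk.x - rk.x)


def shoulder_width(frame: PoseFrame, min_confidence: float = DEFAULT_CLEANING.min_confidence) -> float:
    """Horizontal shoulder separation in px; NaN if either shoulder is low-confidence."""
    return _pair_x_separation(frame, "left_shoulder", "right_shoulder", min_confidence)


def knee_width(frame: PoseFrame, min_confidence: float = DEFAULT_CLEANING.min_confidence) -> float:
    """Horizontal knee separation in px; NaN if either knee is low-confidence."""
    return _pair_x_separation(frame, "left_knee", "right_knee", min_confidence)


def hip_elevation(frame: PoseFrame, min_confidence: float = DEFAULT_CLEANING.min_confidence) -> float:
    """Hip-midpoint height above the knee midpoint, px (y-down image frame).

    Positive when the hip is above the knee; 0 at parallel; negative below.
    NaN if any of the four hip/knee keypoints falls below the confidence
    threshold.
    """
    parts = ("left_hip", "right_hip", "left_knee", "right_knee")
    kps = [frame[p] for p in parts]
    if any(k.confidence < min_confidence for k in kps):
        return math.nan
    hip_y = (kps[0].y + kps[1].y) / 2.0
    knee_y = (kps[2].y + kps[3].y) / 2.0
    return knee_y - hip_y


def _interpolate_gaps(t: np.ndarray, v: np.ndarray, max_gap: float, what: str) -> np.ndarray:
    """Linearly bridge NaN runs no longer than ``max_gap`` seconds.

    Leading/trailing NaN runs are held at the nearest defined value, subject
    to the same gap limit.
    """
    defined = np.isfinite(v)
    if not defined.any():
        raise UnusableSequenceError(f"no confident samples for {what}")
    if defined.all():
        return v
    idx = np.flatnonzero(defined)
    # check every NaN run length in seconds
    gaps = np.flatnonzero(~defined)
    run_start = None
    for i in range(len(v)):
        if not defined[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            lo = t[run_start - 1] if run_start > 0 else t[0]
            if t[i] - lo > max_gap + 1e-12:
                raise UnusableSequenceError(
                    f"{what}: low-confidence gap of {t[i] - lo:.3f} s exceeds max_gap={max_gap} s"
                )
            run_start = None
    if run_start is not None:  # trailing run
        lo = t[run_start - 1] if run_start > 0 else t[0]
        if t[-1] - lo > max_gap + 1e-12:
            raise UnusableSequenceError(
                f"{what}: trailing low-confidence gap exceeds max_gap={max_gap} s"
            )
    out = v.copy()
    out[~defined] = np.interp(t[~defined], t[defined], v[defined])
    return out


def derive_series(seq: PoseSequence, cfg: CleaningConfig | None = None) -> KinematicSeries:
    """Turn a pose sequence into cleaned, uniformly sampled kinematic signals.

    Pipeline: per-frame extraction with confidence masking → linear
    interpolation of short gaps → resampling onto a uniform grid at
    ``seq.nominal_fps`` → moving-average smoothing → normalisation
    (knee ratio in %, hip height relative to the standing baseline).

    Raises :class:`UnusableSequenceError` when a signal has no confident
    samples or a gap longer than ``cfg.max_gap``, and
    :class:`DegeneratePostureError` when the standing baseline hip
    elevation is not positive.
    """
    cfg = cfg or DEFAULT_CLEANING
    t_raw = np.asarray(seq.timestamps, dtype=float)
    ws = np.array([shoulder_width(f, cfg.min_confidence) for f in seq.frames])
    wk = np.array([knee_width(f, cfg.min_confidence) for f in seq.frames])
    he = np.array([hip_elevation(f, cfg.min_confidence) for f in seq.frames])

    ws = _interpolate_gaps(t_raw, ws, cfg.max_gap, "shoulder width")
    wk = _interpolate_gaps(t_raw, wk, cfg.max_gap, "knee width")
    he = _interpolate_gaps(t_raw, he, cfg.max_gap, "hip elevation")

    fps = seq.nominal_fps
    n = int(math.floor((t_raw[-1] - t_raw[0]) * fps + 1e-9)) + 1
    if n < 2:
        raise UnusableSequenceError("sequence too short to resample (< 2 grid samples)")
    t = t_raw[0] + np.arange(n) / fps
    ws = np.interp(t, t_raw, ws)
    wk = np.interp(t, t_raw, wk)
    he = np.interp(t, t_raw, he)

    win = int(round(cfg.smoothing_window * fps))
    if win > 1:
        ws = uniform_filter1d(ws, win, mode="nearest")
        wk = uniform_filter1d(wk, win, mode="nearest")
        he = uniform_filter1d(he, win, mode="nearest")

    with np.errstate(divide="ignore", invalid="ignore"):
        knee_ratio = np.where(ws > 0, wk / ws * 100.0, np.nan)

    base_mask = t - t[0] <= BASELINE_WINDOW_S + 1e-9
    baseline = float(np.median(he[base_mask]))
    if baseline <= 0:
        raise DegeneratePostureError(
            f"baseline hip elevation {baseline:.2f} px is not positive; "
            "the exerciser must start standing"
        )
    hip_norm = he / baseline * 100.0

    return KinematicSeries(
        t=t,
        width_shoulder=ws,
        width_knee=wk,
        knee_ratio=knee_ratio,
        hip_elev=he,
        hip_norm=hip_norm,
        baseline_hip=baseline,
        fps=fps,
    )
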