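"""Synthetic camera-facing squat kinematics with known ground truth.

The simulator emits 17-keypoint pose sequences shaped like what a pose
estimator returns for a person facing the camera and performing paced
body-weight squats: the hip midpoint descends and ascends on a cosine over
each 6-s round (down in 3 s, up in 3 s), knees and shoulders keep fixed
horizontal separations, and the remaining keypoints ride a simple
articulated template (rigid torso, arms held parallel to the ground, head
above the shoulders).  Because the hip trajectory is exactly the optimal
cadence cosine, the default profile is analytically a maximum-score set,
and each preset degrades exactly one quality dimension.

Ground truth: with depth fraction ``d`` the normalised hip height sweeps
100% → 100·d % → 100% each round; the knee/shoulder ratio is
``stance_ratio × 100`` %; a ``tempo_scale`` of s makes the actual cadence
``6·s`` seconds against the fixed 6-s scoring clock.

All randomness (keypoint jitter) comes from a seeded generator, so equal
profiles produce byte-identical serialised output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import UnknownPresetError
from .keypoints_io import Keypoint, PoseFrame, PoseSequence

# Image-frame layout constants (a ~640x480 camera view, y down).
_CX = 320.0           # body midline, px
_KNEE_Y = 370.0       # knee height, px (kept fixed by the template)
_ANKLE_Y = 450.0
_TORSO_LEN = 110.0    # hip to shoulder, px
_HEAD_RISE = 45.0     # shoulder to nose, px
_HIP_WIDTH_FRAC = 0.8  # hip separation as a fraction of shoulder separation
_CONFIDENCE = 0.9


@dataclass(frozen=True)
class SquatProfile:
    """Simulator parameters; the defaults are an ideal, paced set.

    depth_frac: target minimum of the normalised hip height, as a fraction
        of the standing baseline (−0.1 = just below parallel, a full squat).
    stance_ratio: knee/shoulder width ratio (1.10 = knees slightly wider).
    tempo_scale: actual cadence over the nominal 6-s cadence (0.5 = squats
        twice as fast as the pacing clock).
    phase_offset: seconds of standing still before the first descent.
    noise_sd: standard deviation of i.i.d. Gaussian keypoint jitter, px.
    """

    depth_frac: float = -0.1
    stance_ratio: float = 1.10
    tempo_scale: float = 1.0
    phase_offset: float = 0.0
    noise_sd: float = 0.0
    fps: float = 30.0
    n_rounds: int = 10
    round_duration: float = 6.0
    baseline_hip_px: float = 120.0
    shoulder_px: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.shoulder_px <= 0:
            raise ValueError("shoulder_px must be > 0")
        if self.baseline_hip_px <= 0:
            raise ValueError("baseline_hip_px must be > 0")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tempo_scale <= 0:
            raise ValueError("tempo_scale must be > 0")
        if self.phase_offset < 0:
            raise ValueError("phase_offset must be >= 0")


PRESETS: dict[str, SquatProfile] = {
    # every index maximal: ratio 110%, depth -10%, exact 6-s cosine cadence
    "ideal": SquatProfile(),
    # never descends past 60% of baseline -> hip-position score 0
    "shallow": SquatProfile(depth_frac=0.6),
    # knees narrower than shoulders (ratio 90%) -> knee-width score 0
    "narrow": SquatProfile(stance_ratio=0.9),
    # ratio 180% (>= 175%) -> knee-width score 0
    "wide": SquatProfile(stance_ratio=1.8),
    # squats on a 3-s cadence against the 6-s clock -> rhythm score drops
    "rushed": SquatProfile(tempo_scale=0.5),
    # 2 px of keypoint jitter on an otherwise ideal set
    "noisy": SquatProfile(noise_sd=2.0),
}


def preset(name: str, **overrides) -> SquatProfile:
    """Look up a named preset, optionally overriding individual fields."""
    try:
        prof = PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(prof, **overrides) if overrides else prof


def _hip_elevation_curve(t: np.ndarray, p: SquatProfile) -> np.ndarray:
    """Hip height above the knee, px, over real time ``t``.

    Standing until ``phase_offset``, then
    ``baseline * [(1+d)/2 + (1-d)/2 * cos(pi * t' / 3)]`` with the round
    clock ``t'`` running at ``1 / tempo_scale`` of real time.
    """
    d = p.depth_frac
    u = np.maximum(0.0, t - p.phase_offset) / p.tempo_scale
    shape = (1.0 + d) / 2.0 + (1.0 - d) / 2.0 * np.cos(np.pi * u / (p.round_duration / 2.0))
    return p.baseline_hip_px * shape


def simulate_squat(profile: SquatProfile | None = None) -> PoseSequence:
    """Generate a pose sequence for one simulated squat set."""
    p = profile or SquatProfile()
    duration = p.phase_offset + p.n_rounds * p.round_duration
    n = int(round(duration * p.fps)) + 1
    t = np.arange(n) / p.fps
    elev = _hip_elevation_curve(t, p)

    half_sh = p.shoulder_px / 2.0
    half_knee = p.stance_ratio * p.shoulder_px / 2.0
    half_hip = _HIP_WIDTH_FRAC * half_sh

    hip_y = _KNEE_Y - elev
    shoulder_y = hip_y - _TORSO_LEN
    nose_y = shoulder_y - _HEAD_RISE

    rng = np.random.default_rng(p.seed)
    frames = []
    for i in range(n):
        sy, hy, ny = shoulder_y[i], hip_y[i], nose_y[i]
        pts = {
            "nose": (_CX, ny),
            "left_eye": (_CX + 10.0, ny - 5.0),
            "right_eye": (_CX - 10.0, ny - 5.0),
            "left_ear": (_CX + 20.0, ny),
            "right_ear": (_CX - 20.0, ny),
            "left_shoulder": (_CX + half_sh, sy),
            "right_shoulder": (_CX - half_sh, sy),
            # arms held parallel to the ground at shoulder height
            "left_elbow": (_CX + half_sh + 45.0, sy),
            "right_elbow": (_CX - half_sh - 45.0, sy),
            "left_wrist": (_CX + half_sh + 90.0, sy),
            "right_wrist": (_CX - half_sh - 90.0, sy),
            "left_hip": (_CX + half_hip, hy),
            "right_hip": (_CX - half_hip, hy),
            "left_knee": (_CX + half_knee, _KNEE_Y),
            "right_knee": (_CX - half_knee, _KNEE_Y),
            "left_ankle": (_CX + half_knee, _ANKLE_Y),
            "right_ankle": (_CX - half_knee, _ANKLE_Y),
        }
        if p.noise_sd > 0:
            jit = rng.normal(0.0, p.noise_sd, size=(len(pts), 2))
        else:
            jit = np.zeros((len(pts), 2))
        kps = {
            name: Keypoint(name, float(x + jit[j, 0]), float(y + jit[j, 1]), _CONFIDENCE)
            for j, (name, (x, y)) in enumerate(pts.items())
        }
        frames.append(PoseFrame(float(t[i]), kps))
    return PoseSequence(frames, nominal_fps=p.fps, source_id=f"simulated(seed={p.seed})")
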