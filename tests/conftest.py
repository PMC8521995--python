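import math

import pytest

from squatscore import (
    PART_NAMES,
    Keypoint,
    PoseFrame,
    PoseSequence,
    SurveyRecord,
    derive_series,
    preset,
    simulate_squat,
)

# A standing template in image coordinates (y down), used to build
# hand-crafted frames for unit tests.
STANDING_XY = {
    "nose": (320, 105),
    "left_eye": (330, 100),
    "right_eye": (310, 100),
    "left_ear": (340, 105),
    "right_ear": (300, 105),
    "left_shoulder": (360, 150),
    "right_shoulder": (280, 150),
    "left_elbow": (405, 150),
    "right_elbow": (235, 150),
    "left_wrist": (450, 150),
    "right_wrist": (190, 150),
    "left_hip": (352, 260),
    "right_hip": (288, 260),
    "left_knee": (364, 370),
    "right_knee": (276, 370),
    "left_ankle": (364, 450),
    "right_ankle": (276, 450),
}


def make_frame(t=0.0, overrides=None, confidence=0.9):
    """Build a full 17-part frame; overrides maps part -> (x, y[, score])."""
    overrides = overrides or {}
    kps = {}
    for name in PART_NAMES:
        x, y = STANDING_XY[name]
        score = confidence
        if name in overrides:
            spec = overrides[name]
            x, y = spec[0], spec[1]
            if len(spec) > 2:
                score = spec[2]
        kps[name] = Keypoint(name, float(x), float(y), float(score))
    return PoseFrame(t, kps)


def standing_sequence(n_frames=60, fps=30.0):
    """A motionless standing pose, n_frames long."""
    return PoseSequence(
        [make_frame(i / fps) for i in range(n_frames)], nominal_fps=fps
    )


@pytest.fixture(scope="session")
def ideal_sequence():
    return simulate_squat(preset("ideal"))


@pytest.fixture(scope="session")
def ideal_series(ideal_sequence):
    return derive_series(ideal_sequence)


def _records(n, age, gender, change, habit):
    """n survey records with a frequency/duration pair realising the habit."""
    if habit == "regular":
        freq, dur = "over 5 times/week", "over 60 min"  # 1200 min/month
    else:
        freq, dur = "1-2 times/month", "less than 5 min"  # 7.5 min/month
    return [SurveyRecord(age, gender, change, freq, dur) for _ in range(n)]


@pytest.fixture(scope="session")
def cohort_records():
    """200 survey records reproducing the published per-group marginal counts.

    Gender, exercise-change and habit are independent marginals within each
    age group, so assigning them independently reproduces every printed
    percentage.  Younger: n=105, 61 men, 20/45/40 increased/not/decreased,
    53 regular.  Middle: n=58, 22 men, 14/21/23, 24 regular.  Older: n=37,
    20 men, 8/16/13, 25 regular.
    """
    records = []
    specs = [  # (n, age, men, increased, not_changed, decreased, regular)
        (105, 25, 61, 20, 45, 40, 53),
        (58, 47, 22, 14, 21, 23, 24),
        (37, 75, 20, 8, 16, 13, 25),
    ]
    for n, age, men, inc, noc, dec, reg in specs:
        genders = ["men"] * men + ["women"] * (n - men)
        changes = ["increased"] * inc + ["not_changed"] * noc + ["decreased"] * dec
        habits = ["regular"] * reg + ["insufficient"] * (n - reg)
        for g, c, h in zip(genders, changes, habits):
            records.extend(_records(1, age, g, c, h))
    return records


def make_round_with_fraction(fraction, n=1000):
    """Hip trace over one 6-s round whose rhythm sits inside the +-0.3
    optimal band for exactly ``fraction`` % of samples.

    Starts from the exact optimal cosine, then pushes selected samples to
    0.6 normalised units away from the optimal curve (out of band) while
    keeping the round's min/max anchored so the rescaling is unchanged.
    """
    import numpy as np

    t = np.linspace(0.0, 6.0, n)
    opt = np.cos(np.pi * t / 3)
    hmin, hmax = 0.0, 100.0
    h = hmin + (opt + 1.0) / 2.0 * (hmax - hmin)
    k = int(round(fraction / 100.0 * n))
    anchors = {0, int(np.argmin(h))}
    candidates = np.array([i for i in range(n) if i not in anchors])
    forced = candidates[: n - k]
    r_out = np.where(opt[forced] >= 0, opt[forced] - 0.6, opt[forced] + 0.6)
    h[forced] = hmin + (r_out + 1.0) / 2.0 * (hmax - hmin)
    return h, t
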