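"""The three-index squat scoring rubric.

Each 6-s repetition round earns points on three indices:

* **Index 1 — knee width** (0–3).  The knee/shoulder width ratio is banded
  per sample (3 points for 100–125%, 2 for 125–150%, 1 for 150–175%, 0
  outside), and the round score is the most frequent per-sample band
  (ties break toward the lower score).
* **Index 2 — hip position** (0–3).  The minimum of the normalised hip
  height within the round: ≤ 0% (at/below parallel, a full-depth squat)
  scores 3, (0, 25]% scores 2, (25, 50]% scores 1, > 50% scores 0.
* **Index 3 — rhythm** (0–4).  The hip trajectory is rescaled to [−1, 1]
  using the round's own min/max and compared against the optimal cadence
  ``cos(πt/3)`` (down in 3 s, up in 3 s).  The in-band fraction — samples
  within ±0.3 of the optimal curve, in the normalised units — is banded:
  ≥ 80% → 4, [60, 80) → 3, [40, 60) → 2, [20, 40) → 1, < 20% → 0.

Round total is 0–10; a 10-round set totals 0–100.  Undefined
(low-confidence) samples are excluded from both the Index-1 mode and the
rhythm sample counts; a round with fewer than half its samples defined is
flagged low-quality in the diagnostics but still scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import KinematicSeries
from .segmentation import RoundWindow, SetConfig, segment_fixed

#: Half-width of the optimal-rhythm band, in the normalised [-1, 1] units.
BAND_HALFWIDTH = 0.3

#: Fraction of defined samples below which a round is flagged low-quality.
MIN_DEFINED_FRACTION = 0.5


def optimal_rhythm(t_rel: np.ndarray | float) -> np.ndarray | float:
    """The optimal rhythm curve cos(πt/3): +1 standing, −1 at 3 s, +1 at 6 s."""
    return np.cos(np.pi * np.asarray(t_rel, dtype=float) / 3.0)


def level_index1(knee_ratio: float) -> int | None:
    """Band a single knee/shoulder ratio sample (in %) into 0–3 points.

    Returns None for undefined (non-finite or non-positive) samples, which
    are excluded from the round mode.
    """
    if not math.isfinite(knee_ratio) or knee_ratio <= 0:
        return None
    if 100.0 <= knee_ratio < 125.0:
        return 3
    if 125.0 <= knee_ratio < 150.0:
        return 2
    if 150.0 <= knee_ratio < 175.0:
        return 1
    return 0


def score_index1(knee_ratios: np.ndarray) -> tuple[int, int | None]:
    """Round score for knee width: the most frequent per-sample band.

    Ties break toward the LOWER score so ambiguity never inflates
    performance.  Returns ``(points, modal_level)``; an all-undefined round
    scores 0 with ``modal_level=None``.
    """
    counts = [0, 0, 0, 0]
    for r in np.asarray(knee_ratios, dtype=float):
        lvl = level_index1(float(r))
        if lvl is not None:
            counts[lvl] += 1
    if sum(counts) == 0:
        return 0, None
    best = max(counts)
    modal = min(l for l in range(4) if counts[l] == best)
    return modal, modal


def score_index2(hip_norm: np.ndarray) -> tuple[int, float]:
    """Round score for hip position, from the minimum normalised hip height (%).

    Returns ``(points, min_hip_norm)``; an all-undefined round scores 0 with
    ``min_hip_norm=nan``.
    """
    v = np.asarray(hip_norm, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return 0, math.nan
    m = float(np.min(v))
    if m <= 0.0:
        return 3, m
    if m <= 25.0:
        return 2, m
    if m <= 50.0:
        return 1, m
    return 0, m


@dataclass
class RhythmTrace:
    """Normalised rhythm vs the optimal cosine within one round."""

    t_rel: np.ndarray
    rhythm: np.ndarray
    optimal: np.ndarray
    in_band: np.ndarray
    n_rhythm: int
    n_all: int
    band_halfwidth: float = BAND_HALFWIDTH
    degenerate: bool = False

    @property
    def in_band_fraction(self) -> float:
        """Percent of defined samples inside the optimal band."""
        if self.n_all == 0:
            return math.nan
        return self.n_rhythm / self.n_all * 100.0


def rhythm_trace(
    hip_elev: np.ndarray,
    t_rel: np.ndarray,
    band_halfwidth: float = BAND_HALFWIDTH,
) -> RhythmTrace:
    """Rescale the hip trajectory to [−1, 1] and compare it to cos(πt/3).

    The rescaling uses the round's own minimum and maximum hip height, so
    the trace always touches −1 and +1.  A motionless round (max == min) is
    degenerate and carries no in-band samples.
    """
    h = np.asarray(hip_elev, dtype=float)
    t_rel = np.asarray(t_rel, dtype=float)
    defined = np.isfinite(h)
    opt = optimal_rhythm(t_rel)
    n_all = int(defined.sum())
    if n_all < 2:
        nanr = np.full_like(t_rel, np.nan)
        return RhythmTrace(t_rel, nanr, opt, np.zeros_like(defined), 0, n_all,
                           band_halfwidth, degenerate=True)
    h_min = float(np.min(h[defined]))
    h_max = float(np.max(h[defined]))
    if h_max <= h_min:
        nanr = np.full_like(t_rel, np.nan)
        return RhythmTrace(t_rel, nanr, opt, np.zeros_like(defined), 0, n_all,
                           band_halfwidth, degenerate=True)
    rhythm = 2.0 * (h - h_min) / (h_max - h_min) - 1.0
    in_band = defined & (np.abs(rhythm - opt) <= band_halfwidth)
    return RhythmTrace(t_rel, rhythm, opt, in_band, int(in_band.sum()), n_all,
                       band_halfwidth)


def score_index3(trace: RhythmTrace) -> int:
    """Round score for rhythm, from the in-band sample fraction."""
    if trace.degenerate or trace.n_all == 0:
        return 0
    f = trace.in_band_fraction
    if f >= 80.0:
        return 4
    if f >= 60.0:
        return 3
    if f >= 40.0:
        return 2
    if f >= 20.0:
        return 1
    return 0


@dataclass
class RoundScore:
    round_index: int
    index1: int
    index2: int
    index3: int
    total: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "round": self.round_index,
            "index1": self.index1,
            "index2": self.index2,
            "index3": self.index3,
            "total": self.total,
            "diagnostics": self.diagnostics,
        }


@dataclass
class SetScore:
    rounds: list[RoundScore]
    sum_index1: int
    sum_index2: int
    sum_index3: int
    grand_total: int

    def to_dict(self) -> dict:
        return {
            "rounds": [r.to_dict() for r in self.rounds],
            "sum_index1": self.sum_index1,
            "sum_index2": self.sum_index2,
            "sum_index3": self.sum_index3,
            "grand_total": self.grand_total,
        }


def _json_safe(x: float) -> float | None:
    return None if not math.isfinite(x) else float(x)


def score_round(
    series: KinematicSeries,
    window: RoundWindow,
    band_halfwidth: float = BAND_HALFWIDTH,
) -> RoundScore:
    """Score one repetition round against all three indices."""
    sl = slice(window.start, window.stop)
    if window.empty:
        return RoundScore(window.round_index, 0, 0, 0, 0, {"empty": True})
    ratios = series.knee_ratio[sl]
    hip_norm = series.hip_norm[sl]
    hip_elev = series.hip_elev[sl]
    t_rel = series.t[sl] - window.t_start

    i1, modal = score_index1(ratios)
    i2, min_hn = score_index2(hip_norm)
    trace = rhythm_trace(hip_elev, t_rel, band_halfwidth)
    i3 = score_index3(trace)

    n_samples = window.n_samples
    n_defined = int(np.isfinite(hip_elev).sum())
    diagnostics = {
        "empty": False,
        "modal_knee_band": modal,
        "min_hip_norm": _json_safe(min_hn),
        "in_band_fraction": _json_safe(trace.in_band_fraction),
        "degenerate_rhythm": trace.degenerate,
        "n_samples": n_samples,
        "n_defined": n_defined,
        "low_quality": n_defined < MIN_DEFINED_FRACTION * n_samples,
    }
    return RoundScore(window.round_index, i1, i2, i3, i1 + i2 + i3, diagnostics)


def score_set(
    series: KinematicSeries,
    cfg: SetConfig | None = None,
    t0: float = 0.0,
    band_halfwidth: float = BAND_HALFWIDTH,
) -> SetScore:
    """Segment the set on the fixed cadence and score every round."""
    windows = segment_fixed(series, cfg, t0)
    rounds = [score_round(series, w, band_halfwidth) for w in windows]
    return SetScore(
        rounds=rounds,
        sum_index1=sum(r.index1 for r in rounds),
        sum_index2=sum(r.index2 for r in rounds),
        sum_index3=sum(r.index3 for r in rounds),
        grand_total=sum(r.total for r in rounds),
    )
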