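"""Partition a fixed-cadence squat set into its repetition rounds.

The deployed system paces the exerciser with a counting voice: one
repetition round lasts 6 s (descend in 3 s, ascend in 3 s) and one set is
10 rounds = 60 s.  Segmentation is therefore a fixed clock, not valley
detection; :func:`detect_start` only places the clock's origin on recorded
files, where no pacing voice exists.

Windows are half-open ``[t_start, t_end)``: a sample exactly on a boundary
belongs to the later round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import StartNotFoundError, TooShortError
from .kinematics import KinematicSeries


@dataclass(frozen=True)
class SetConfig:
    """Set structure: number of rounds and the fixed round duration (s)."""

    n_rounds: int = 10
    round_duration: float = 6.0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.round_duration <= 0:
            raise ValueError("round_duration must be > 0")

    @property
    def set_duration(self) -> float:
        return self.n_rounds * self.round_duration


DEFAULT_SET = SetConfig()


@dataclass(frozen=True)
class RoundWindow:
    """One repetition round: its time window and the sample slice it maps to."""

    round_index: int  # 1-based
    t_start: float
    t_end: float
    start: int  # slice start into the KinematicSeries arrays
    stop: int   # slice stop (exclusive)

    @property
    def empty(self) -> bool:
        return self.stop <= self.start

    @property
    def n_samples(self) -> int:
        return max(0, self.stop - self.start)


def segment_fixed(
    series: KinematicSeries,
    cfg: SetConfig | None = None,
    t0: float = 0.0,
) -> list[RoundWindow]:
    """Cut ``n_rounds`` contiguous, non-overlapping windows of fixed duration.

    The series should cover ``[t0, t0 + set_duration]``; a shorter series is
    accepted with a warning as long as it spans at least one round, and
    trailing rounds without samples come back flagged empty.
    """
    cfg = cfg or DEFAULT_SET
    t = series.t
    coverage = t[-1] - t0
    if coverage < cfg.round_duration - 1.0 / series.fps:
        raise TooShortError(
            f"series covers {coverage:.2f} s past t0={t0:.2f}, "
            f"less than one {cfg.round_duration:.0f}-s round"
        )
    if coverage < cfg.set_duration - 1.0 / series.fps:
        warnings.warn(
            f"series covers only {coverage:.1f} s of the "
            f"{cfg.set_duration:.0f}-s set; trailing rounds will be empty",
            stacklevel=2,
        )
    windows = []
    for i in range(cfg.n_rounds):
        ts = t0 + i * cfg.round_duration
        te = ts + cfg.round_duration
        start = int(np.searchsorted(t, ts, side="left"))
        stop = int(np.searchsorted(t, te, side="left"))
        windows.append(RoundWindow(i + 1, ts, te, start, stop))
    return windows


def detect_start(
    series: KinematicSeries,
    threshold: float = 10.0,
    round_duration: float = 6.0,
) -> float:
    """Locate the start of the first repetition on a recorded file.

    The cue is the first hip descent: the signal must fall below
    ``(100 - threshold)%`` of the standing baseline.  The clock origin is
    then placed half a descent (``round_duration / 4``, i.e. 1.5 s for the
    6-s cadence) before the moment the hip crosses the half-depth level —
    for a cosine descent that crossing happens exactly mid-descent, so the
    estimate is exact on clean input.  The result is clipped at 0.

    Raises :class:`StartNotFoundError` if the hip never descends below the
    threshold.
    """
    hn = series.hip_norm
    t = series.t
    below = np.flatnonzero(hn < 100.0 - threshold)
    if below.size == 0:
        raise StartNotFoundError(
            f"hip never descends below {100.0 - threshold:.0f}% of baseline"
        )
    i_cross = below[0]
    # depth of the first repetition: minimum within one descent of the cue
    seek = (t >= t[i_cross]) & (t <= t[i_cross] + round_duration / 2.0)
    depth = float(np.min(hn[seek]))
    half_level = (100.0 + depth) / 2.0
    i_half = int(np.flatnonzero(hn <= half_level)[0])
    return max(0.0, float(t[i_half]) - round_duration / 4.0)
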