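"""Score-driven audio feedback: the volume envelope.

Performance is sonified by mixing background music (BGM) against masking
noise: the better the round, the clearer the music.  The mapping is linear
in the round total over its 0–10 range — a round scoring 8/10 plays BGM at
80% of maximum and noise at 20% — so BGM and noise volumes always sum to
100%.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import SetScore

#: Maximum attainable round total (Index 1 + Index 2 + Index 3).
MAX_ROUND_TOTAL = 10


@dataclass(frozen=True)
class RoundVolume:
    round_index: int
    bgm_pct: float
    noise_pct: float


@dataclass
class VolumeEnvelope:
    """Per-round BGM / noise volumes, in percent of maximum."""

    rounds: list[RoundVolume]

    def __iter__(self):
        return iter(self.rounds)

    def __len__(self) -> int:
        return len(self.rounds)

    def to_rows(self) -> list[dict]:
        return [
            {"round": r.round_index, "bgm_pct": r.bgm_pct, "noise_pct": r.noise_pct}
            for r in self.rounds
        ]


def volume_envelope(set_score: SetScore) -> VolumeEnvelope:
    """Map each round's total score to its BGM / noise volume split."""
    rounds = []
    for r in set_score.rounds:
        bgm = r.total / MAX_ROUND_TOTAL * 100.0
        rounds.append(RoundVolume(r.round_index, bgm, 100.0 - bgm))
    return VolumeEnvelope(rounds)
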