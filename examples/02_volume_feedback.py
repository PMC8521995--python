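"""Map round scores to the audio-feedback volume envelope.

The better a round, the clearer the music: BGM volume is the round total
as a percentage of the 10-point maximum, masking noise is the complement,
and the two always sum to 100%.
"""

from squatscore import derive_series, preset, score_set, simulate_squat, volume_envelope

# a set whose depth degrades over the final rounds
seq = simulate_squat(preset("ideal"))
series = derive_series(seq)
ss = score_set(series)

# hand-degrade a couple of rounds to show the mapping (normally the scores
# come straight from the pipeline)
from squatscore.scoring import RoundScore, SetScore

rounds = list(ss.rounds)
rounds[3] = RoundScore(4, 3, 2, 3, 8)
rounds[7] = RoundScore(8, 2, 1, 2, 5)
ss = SetScore(rounds, 0, 0, 0, sum(r.total for r in rounds))

print("round  total  BGM%  noise%")
for r, v in zip(ss.rounds, volume_envelope(ss)):
    print(f"{r.round_index:5d}  {r.total:5d}  {v.bgm_pct:4.0f}  {v.noise_pct:6.0f}")

# Round 4 scored 8/10, so its music plays at 80% of maximum volume with
# 20% masking noise; a perfect round plays clean music at full volume.
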