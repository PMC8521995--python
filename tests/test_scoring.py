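import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from squatscore import (
    Keypoint,
    PoseFrame,
    PoseSequence,
    SetConfig,
    derive_series,
    level_index1,
    optimal_rhythm,
    preset,
    rhythm_trace,
    score_index1,
    score_index2,
    score_index3,
    score_round,
    score_set,
    segment_fixed,
    simulate_squat,
)

from conftest import make_round_with_fraction, standing_sequence


class TestKneeWidthBanding:
    @pytest.mark.parametrize(
        "ratio,points",
        [
            (110.0, 3),
            (100.0, 3),
            (124.999, 3),
            (125.0, 2),
            (149.999, 2),
            (150.0, 1),
            (174.999, 1),
            (175.0, 0),
            (99.999, 0),
            (90.0, 0),
            (200.0, 0),
        ],
    )
    def test_band_boundaries(self, ratio, points):
        assert level_index1(ratio) == points

    def test_undefined_sample_excluded(self):
        assert level_index1(float("nan")) is None
        assert level_index1(-5.0) is None

    def test_mode_over_round(self):
        assert score_index1(np.full(180, 110.0))[0] == 3
        ratios = np.concatenate([np.full(60, 110.0), np.full(120, 130.0)])
        assert score_index1(ratios)[0] == 2

    def test_tie_breaks_toward_lower_score(self):
        ratios = np.concatenate([np.full(90, 110.0), np.full(90, 130.0)])
        assert score_index1(ratios)[0] == 2

    def test_all_undefined_round_scores_zero(self):
        points, modal = score_index1(np.full(10, np.nan))
        assert points == 0 and modal is None


class TestHipPositionBanding:
    @pytest.mark.parametrize(
        "minimum,points",
        [(-10.0, 3), (0.0, 3), (10.0, 2), (25.0, 2), (25.01, 1), (50.0, 1), (60.0, 0)],
    )
    def test_band_boundaries(self, minimum, points):
        trace = np.linspace(100.0, minimum, 50)
        assert score_index2(trace)[0] == points

    def test_all_undefined_scores_zero(self):
        points, m = score_index2(np.full(5, np.nan))
        assert points == 0 and math.isnan(m)


class TestRhythm:
    def test_normalisation_endpoints(self):
        t = np.linspace(0, 6, 100)
        h = 50 + 30 * np.cos(np.pi * t / 3)
        trace = rhythm_trace(h, t)
        assert trace.rhythm[np.argmax(h)] == pytest.approx(1.0)
        assert trace.rhythm[np.argmin(h)] == pytest.approx(-1.0)

    def test_optimal_curve_endpoints(self):
        assert optimal_rhythm(0.0) == pytest.approx(1.0)
        assert optimal_rhythm(3.0) == pytest.approx(-1.0)
        assert optimal_rhythm(6.0) == pytest.approx(1.0)

    def test_cosine_trajectory_fully_in_band(self):
        t = np.arange(0, 6, 1 / 30)
        h = 120 * (0.45 + 0.55 * np.cos(np.pi * t / 3))
        trace = rhythm_trace(h, t)
        assert trace.n_rhythm == trace.n_all == len(t)
        assert score_index3(trace) == 4

    def test_constant_trajectory_is_degenerate(self):
        t = np.arange(0, 6, 1 / 30)
        trace = rhythm_trace(np.full_like(t, 80.0), t)
        assert trace.degenerate
        assert score_index3(trace) == 0

    @pytest.mark.parametrize(
        "fraction,points",
        [(85.0, 4), (80.0, 4), (79.9, 3), (60.0, 3), (59.9, 2), (40.0, 2), (39.9, 1), (20.0, 1), (19.9, 0)],
    )
    def test_in_band_fraction_banding(self, fraction, points):
        trace = rhythm_trace(*make_round_with_fraction(fraction))
        assert trace.in_band_fraction == pytest.approx(fraction, abs=0.05)
        assert score_index3(trace) == points


class TestOracleEquivalence:
    """Vectorised scoring must match a one-sample-at-a-time recomputation."""

    def _brute_index1(self, ratios):
        counts = Counter()
        for r in ratios:
            if math.isfinite(r) and r > 0:
                if 100 <= r < 125:
                    counts[3] += 1
                elif 125 <= r < 150:
                    counts[2] += 1
                elif 150 <= r < 175:
                    counts[1] += 1
                else:
                    counts[0] += 1
        if not counts:
            return 0
        best = max(counts.values())
        return min(l for l, c in counts.items() if c == best)

    def _brute_index3(self, h, t, band=0.3):
        vals = [(hh, tt) for hh, tt in zip(h, t) if math.isfinite(hh)]
        if len(vals) < 2:
            return None, None
        hmin = min(v for v, _ in vals)
        hmax = max(v for v, _ in vals)
        if hmax <= hmin:
            return None, None
        n_in = 0
        for hh, tt in vals:
            r = 2 * (hh - hmin) / (hmax - hmin) - 1
            if abs(r - math.cos(math.pi * tt / 3)) <= band:
                n_in += 1
        return n_in, len(vals)

    def test_random_rounds_match_brute_force(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n = rng.integers(2, 60)
            t = np.sort(rng.uniform(0, 6, n))
            h = rng.uniform(-20, 120, n)
            h[rng.random(n) < 0.1] = np.nan
            ratios = rng.uniform(50, 220, n)
            ratios[rng.random(n) < 0.1] = np.nan

            assert score_index1(ratios)[0] == self._brute_index1(ratios)

            trace = rhythm_trace(h, t)
            n_in, n_all = self._brute_index3(h, t)
            if n_in is None:
                assert trace.degenerate or trace.n_all < 2
            else:
                assert (trace.n_rhythm, trace.n_all) == (n_in, n_all)


class TestBoundsAndMonotonicity:
    @settings(max_examples=200, deadline=None)
    @given(
        h=hnp.arrays(np.float64, st.integers(2, 40),
                     elements=st.floats(-50, 150, allow_nan=False)),
        ratios=hnp.arrays(np.float64, st.integers(1, 40),
                          elements=st.floats(0, 300, allow_nan=False)),
    )
    def test_score_bounds_on_random_rounds(self, h, ratios):
        t = np.linspace(0, 6, len(h))
        i1 = score_index1(ratios)[0]
        i2 = score_index2(h)[0]
        i3 = score_index3(rhythm_trace(h, t))
        assert 0 <= i1 <= 3
        assert 0 <= i2 <= 3
        assert 0 <= i3 <= 4
        assert 0 <= i1 + i2 + i3 <= 10

    def test_index2_monotone_in_depth(self):
        minima = np.linspace(80, -20, 60)
        scores = [score_index2(np.array([100.0, m]))[0] for m in minima]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_index3_monotone_in_band_fraction(self):
        prev = -1
        for fraction in range(2, 101, 2):
            s = score_index3(rhythm_trace(*make_round_with_fraction(float(fraction))))
            assert s >= prev
            prev = s


class TestRoundAndSet:
    def test_ideal_round_scores_ten(self, ideal_series):
        w = segment_fixed(ideal_series, SetConfig())[0]
        rs = score_round(ideal_series, w)
        assert (rs.index1, rs.index2, rs.index3, rs.total) == (3, 3, 4, 10)

    def test_empty_round_scores_zero(self, ideal_series):
        from squatscore.segmentation import RoundWindow

        rs = score_round(ideal_series, RoundWindow(5, 24.0, 30.0, 100, 100))
        assert rs.total == 0
        assert rs.diagnostics["empty"]

    def test_ideal_set_scores_one_hundred(self, ideal_series):
        ss = score_set(ideal_series)
        assert ss.grand_total == 100
        assert (ss.sum_index1, ss.sum_index2, ss.sum_index3) == (30, 30, 40)
        assert ss.grand_total == sum(r.total for r in ss.rounds)

    def test_totals_scale_invariant(self, ideal_sequence):
        def scaled(seq, s):
            frames = [
                PoseFrame(
                    f.timestamp,
                    {
                        n: Keypoint(n, k.x * s + 13.0, k.y * s - 7.0, k.confidence)
                        for n, k in f.keypoints.items()
                    },
                )
                for f in seq.frames
            ]
            return PoseSequence(frames, seq.nominal_fps)

        a = score_set(derive_series(ideal_sequence))
        b = score_set(derive_series(scaled(ideal_sequence, 2.5)))
        assert [r.total for r in a.rounds] == [r.total for r in b.rounds]

    def test_motionless_set_degenerate_throughout(self):
        series = derive_series(standing_sequence(n_frames=1801))
        ss = score_set(series)
        for r in ss.rounds:
            assert r.index2 == 0 and r.index3 == 0
            assert r.diagnostics["degenerate_rhythm"]
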