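"""Sequence-MAP trellis decoding against exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifill import (
    MarkovParams,
    branch_metric,
    brute_force_map,
    decode_segment,
    segment_decompose,
    smap_decode,
)

from conftest import all_binary_sequences


class TestBranchMetric:
    @pytest.mark.parametrize(
        "m_prev, m, d, expected",
        [
            (1, 1, 0, 0.45),  # alpha * (1 - retention)
            (1, 0, 0, 0.10),  # (1 - alpha) * 1
            (1, 1, 1, 0.45),  # alpha * retention
            (0, 1, 1, 0.05),  # (1 - beta) * retention
        ],
    )
    def test_values_at_realistic_params(self, realistic_params, m_prev, m, d, expected):
        assert branch_metric(realistic_params, m_prev, m, d, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("m_prev", [0, 1])
    def test_channel_never_creates_marks(self, realistic_params, m_prev):
        assert branch_metric(realistic_params, m_prev, 0, 1, 0.5) == 0.0


class TestSegmentDecompose:
    def test_two_segments(self):
        segs = segment_decompose(np.array([1, 0, 0, 1, 0, 1], dtype=np.int8))
        assert [(s.start, s.end, s.k) for s in segs] == [(0, 3, 2), (3, 5, 1)]

    @pytest.mark.parametrize(
        "daughter",
        [[0, 0, 1, 1, 0, 0], [1, 1, 1], [0, 0, 0]],
    )
    def test_nothing_to_decode(self, daughter):
        assert segment_decompose(np.array(daughter, dtype=np.int8)) == []

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_segments_disjoint_ordered_flanked(self, bits):
        d = np.array(bits, dtype=np.int8)
        segs = segment_decompose(d)
        prev_end = -1
        for s in segs:
            assert d[s.start] == 1 and d[s.end] == 1
            assert np.all(d[s.start + 1 : s.end] == 0)
            assert s.k >= 1
            assert s.start >= prev_end
            prev_end = s.end


class TestDecodeSegment:
    def test_short_island_filled(self, realistic_params):
        # all-ones metric 0.45^4 ~ 0.0410 beats all-zeros 0.1*0.81*0.05
        assert np.all(decode_segment(realistic_params, 3) == 1)

    def test_long_island_left_empty(self, realistic_params):
        assert np.all(decode_segment(realistic_params, 10) == 0)

    def test_lossless_channel_trusts_observations(self):
        for k in (1, 3, 7):
            assert np.all(decode_segment(MarkovParams(0.7, 0.4), k, retention=1.0) == 0)

    @pytest.mark.parametrize("k", range(1, 11))
    def test_matches_enumeration_over_interior_paths(self, k):
        """Viterbi argmax equals explicit max over all 2^k interior paths."""
        params = MarkovParams(0.85, 0.6)
        best_path, best_score = None, -np.inf
        for bits in itertools.product((0, 1), repeat=k):
            prev, score = 1, 0.0
            for m in bits:
                score += np.log(branch_metric(params, prev, m, 0, 0.5))
                prev = m
            score += np.log(branch_metric(params, prev, 1, 1, 0.5))
            if score > best_score:
                best_path, best_score = bits, score
        assert np.array_equal(decode_segment(params, k), np.array(best_path))


class TestSmapDecode:
    def test_all_ones_fixed_point(self, realistic_params):
        d = np.ones(6, dtype=np.int8)
        assert np.array_equal(smap_decode(realistic_params, d), d)

    def test_fills_short_flanked_island(self, realistic_params):
        out = smap_decode(realistic_params, np.array([1, 0, 0, 0, 1], dtype=np.int8))
        assert np.array_equal(out, np.ones(5, dtype=np.int8))

    def test_all_zeros_unchanged(self, realistic_params):
        d = np.zeros(7, dtype=np.int8)
        assert np.array_equal(smap_decode(realistic_params, d), d)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50), st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_monotone_trust(self, bits, alpha, beta):
        """Observed 1s survive; nothing is filled outside flanked runs."""
        d = np.array(bits, dtype=np.int8)
        out = smap_decode(MarkovParams(alpha, beta), d)
        assert np.all(out >= d)
        ones = np.flatnonzero(d == 1)
        if ones.size:
            assert np.all(out[: ones[0]] == d[: ones[0]])
            assert np.all(out[ones[-1] + 1 :] == d[ones[-1] + 1 :])
        else:
            assert np.array_equal(out, d)


class TestBruteForceOracle:
    def test_trivial_two_ones(self, realistic_params):
        d = np.array([1, 1], dtype=np.int8)
        assert np.array_equal(brute_force_map(realistic_params, d), d)

    def test_single_zero_filled_when_g1_positive(self, realistic_params):
        out = brute_force_map(realistic_params, np.array([1, 0, 1], dtype=np.int8))
        assert np.array_equal(out, np.ones(3, dtype=np.int8))

    def test_refuses_combinatorial_explosion(self, realistic_params):
        with pytest.raises(ValueError):
            brute_force_map(realistic_params, np.zeros(30, dtype=np.int8), fill_boundary=True)

    def test_random_instances_match_trellis(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            alpha, beta = rng.uniform(0.05, 0.95, 2)
            params = MarkovParams(alpha, beta)
            n = int(rng.integers(3, 15))
            d = np.zeros(n, dtype=np.int8)
            d[rng.random(n) < 0.5] = 1
            d[0] = d[-1] = 1  # leading and trailing observed ones
            assert np.array_equal(
                smap_decode(params, d), brute_force_map(params, d, fill_boundary=True)
            )

    def test_segmentwise_equals_joint_enumeration(self):
        """Decoding each flanked run separately equals joint decoding."""
        params = MarkovParams(0.8, 0.7)
        for daughter in (
            [1, 0, 1, 0, 0, 1, 0, 0, 0, 1],
            [0, 1, 0, 0, 1, 0, 1, 0],
            [1, 0, 0, 0, 0, 1, 0, 1, 1, 0, 1],
        ):
            d = np.array(daughter, dtype=np.int8)
            assert np.array_equal(smap_decode(params, d), brute_force_map(params, d))

    def test_exhaustive_short_daughters(self):
        for params in (MarkovParams(0.9, 0.9), MarkovParams(0.3, 0.8), MarkovParams(0.8, 0.3)):
            for n in range(1, 9):
                for d in all_binary_sequences(n):
                    assert np.array_equal(smap_decode(params, d), brute_force_map(params, d))
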