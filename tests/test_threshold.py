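"""The g_k criterion, k*, regime classification and threshold filling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from epifill import (
    FILL_ALL,
    ChannelSpec,
    MarkovParams,
    ThresholdRule,
    antagonistic_fill,
    classify_region,
    fill_all,
    g_k,
    generate_mother,
    k_star,
    optimal_threshold,
    replicate,
    smap_decode,
    threshold_fill,
)

from conftest import numeric_k_root, region_b_pairs


class TestGk:
    def test_hand_evaluated_margin(self, realistic_params):
        # alpha^2/4 - (1/2)(1-alpha)(1-beta) at alpha = beta = 0.9
        assert g_k(realistic_params, 1) == pytest.approx(0.1975)

    def test_negative_for_alpha_zero(self):
        params = MarkovParams(0.0, 0.6)
        assert all(g_k(params, k) < 0 for k in range(1, 8))

    def test_sign_change_brackets_k_star(self, realistic_params):
        assert g_k(realistic_params, 6) > 0 > g_k(realistic_params, 7)


class TestKStar:
    def test_realistic_value(self, realistic_params):
        assert k_star(realistic_params) == pytest.approx(6.34, abs=0.01)

    def test_closed_form_is_root_of_g(self):
        rng = np.random.default_rng(21)
        for params in region_b_pairs(rng, 50):
            root = k_star(params)
            assert abs(root - numeric_k_root(params, brentq)) < 1e-9 * max(1.0, abs(root))
            if root < 100:  # raw g_k is well-scaled here (no underflow)
                hi = 2.0
                while g_k(params, hi) > 0:
                    hi *= 2
                raw = brentq(lambda k: g_k(params, k), 1.0, hi, xtol=1e-12)
                assert abs(root - raw) < 1e-9

    def test_integer_bracketing(self):
        rng = np.random.default_rng(22)
        for params in region_b_pairs(rng, 50):
            ks = k_star(params)
            if ks >= 1:
                assert g_k(params, math.floor(ks)) > 0
            assert g_k(params, math.floor(ks) + 1) < 0

    def test_no_finite_root_on_boundary(self):
        with pytest.raises(ValueError):
            k_star(MarkovParams(0.9, 0.45))

    def test_region_c_not_fillable(self):
        with pytest.raises(ValueError):
            k_star(MarkovParams(0.1, 0.9))

    def test_diverges_approaching_alpha_equals_two_beta(self):
        assert k_star(MarkovParams(0.89999, 0.45)) > 1e3


class TestRegions:
    @pytest.mark.parametrize(
        "alpha, beta, label",
        [
            (0.9, 0.1, "a"),
            (0.9, 0.9, "b"),  # the biologically realistic regime
            (0.1, 0.9, "c"),
            (0.62, 0.05, "d"),
        ],
    )
    def test_representative_points(self, alpha, beta, label):
        assert classify_region(MarkovParams(alpha, beta)) == label

    def test_alpha_two_beta_line_with_positive_g1_fills_all(self):
        # on alpha = 2*beta the sign of g_k is k-independent
        params = MarkovParams(0.9, 0.45)
        assert classify_region(params) == "a"
        assert optimal_threshold(params).k_t == FILL_ALL

    def test_optimal_threshold_by_region(self, realistic_params):
        assert optimal_threshold(realistic_params).k_t == 6
        assert optimal_threshold(MarkovParams(0.1, 0.9)).k_t == 0


class TestThresholdFill:
    def test_only_short_runs_fill(self):
        out = threshold_fill(np.array([1, 0, 0, 1, 0, 0, 0, 1], dtype=np.int8), ThresholdRule(2))
        assert np.array_equal(out, [1, 1, 1, 1, 0, 0, 0, 1])

    def test_zero_threshold_is_identity(self):
        d = np.array([1, 0, 1, 0, 0, 1], dtype=np.int8)
        assert np.array_equal(threshold_fill(d, ThresholdRule(0)), d)

    def test_boundary_zeros_untouched(self):
        out = threshold_fill(np.array([0, 1, 0, 1, 0], dtype=np.int8), ThresholdRule(5))
        assert np.array_equal(out, [0, 1, 1, 1, 0])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50), st.integers(0, 8))
    @settings(max_examples=80, deadline=None)
    def test_idempotent(self, bits, k_t):
        d = np.array(bits, dtype=np.int8)
        once = threshold_fill(d, ThresholdRule(k_t))
        assert np.array_equal(threshold_fill(once, ThresholdRule(k_t)), once)


class TestFillAll:
    def test_fills_any_interior_length(self):
        d = np.zeros(12, dtype=np.int8)
        d[0] = d[-1] = 1
        assert np.all(fill_all(d) == 1)

    def test_all_zeros_unchanged(self):
        d = np.zeros(5, dtype=np.int8)
        assert np.array_equal(fill_all(d), d)

    def test_boundary_runs_left(self):
        assert np.array_equal(
            fill_all(np.array([0, 0, 1, 0, 1, 0, 0], dtype=np.int8)), [0, 0, 1, 1, 1, 0, 0]
        )


class TestAntagonisticFill:
    def test_concordant_runs_fill(self):
        out = antagonistic_fill([1, 0, 0, 1, 2, 0, 2], ThresholdRule(2))
        assert np.array_equal(out, [1, 1, 1, 1, 2, 2, 2])

    def test_discordant_flanks_never_fill(self):
        d = [1, 0, 2]
        assert np.array_equal(antagonistic_fill(d, ThresholdRule(9)), d)

    def test_threshold_respected(self):
        d = [1, 0, 0, 0, 1]
        assert np.array_equal(antagonistic_fill(d, ThresholdRule(2)), d)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=50), st.integers(0, 8))
    @settings(max_examples=80, deadline=None)
    def test_idempotent_and_mark_destroying_nothing(self, symbols, k_t):
        d = np.array(symbols, dtype=np.int8)
        once = antagonistic_fill(d, ThresholdRule(k_t))
        assert np.array_equal(antagonistic_fill(once, ThresholdRule(k_t)), once)
        # existing marks are never altered
        assert np.all(once[d != 0] == d[d != 0])


class TestSmapEquivalence:
    """The central reduction: threshold filling emulates SMAP decoding."""

    @pytest.mark.parametrize("alpha, beta", [(0.8, 0.9), (0.9, 0.9), (0.85, 0.95)])
    def test_region_b_threshold_equals_smap(self, alpha, beta):
        params = MarkovParams(alpha, beta)
        rule = ThresholdRule(math.floor(k_star(params)))
        rng = np.random.SeedSequence(31).spawn(200)
        for i, ss in enumerate(rng):
            mother = generate_mother(params, 300, ss)
            daughter = replicate(mother, ChannelSpec(0.5), np.random.SeedSequence(10_000 + i))
            assert np.array_equal(
                threshold_fill(daughter, rule), smap_decode(params, daughter)
            )

    def test_region_a_fill_all_equals_smap(self):
        params = MarkovParams(0.9, 0.1)
        rng = np.random.SeedSequence(32).spawn(100)
        for i, ss in enumerate(rng):
            mother = generate_mother(params, 300, ss)
            daughter = replicate(mother, ChannelSpec(0.5), np.random.SeedSequence(20_000 + i))
            assert np.array_equal(fill_all(daughter), smap_decode(params, daughter))
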