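"""Both sign tests: exact binomial (EE) and conditional resampling (exact + MC)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qtlsign import (
    decide,
    orient_dataset,
    qtlst,
    qtlst_conditional_tail,
    qtlst_ee,
    qtlst_ee_pvalue,
    qtlst_exact,
    qtlst_mc,
    signed_half_difference,
)

from _oracles import brute_force_qtlst


def oriented(mags, dirs=None):
    mags = np.asarray(mags, float)
    if dirs is None:
        dirs = np.ones(mags.size, int)
    return orient_dataset(mags, dirs)


class TestEqualEffectsTest:
    @pytest.mark.parametrize(
        "n_plus, n, expected",
        [
            (9, 10, 22 / 1024),
            (8, 10, 112 / 1024),
            (10, 10, 2 / 1024),
            (5, 10, 1.0),
            (0, 10, 2 / 1024),
        ],
    )
    def test_exact_two_sided_values(self, n_plus, n, expected):
        assert qtlst_ee_pvalue(n_plus, n) == expected

    def test_published_rounding(self):
        assert round(qtlst_ee_pvalue(9, 10), 3) == 0.021
        assert round(qtlst_ee_pvalue(8, 10), 2) == 0.11

    @given(st.integers(1, 30), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_in_plus_and_minus_counts(self, n, data):
        k = data.draw(st.integers(0, n))
        assert qtlst_ee_pvalue(k, n) == qtlst_ee_pvalue(n - k, n)

    @given(st.integers(1, 25), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_scipy_binomtest(self, n, data):
        k = data.draw(st.integers(0, n))
        ours = qtlst_ee_pvalue(k, n)
        ref = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)

    @pytest.mark.parametrize("n_plus, n", [(-1, 10), (11, 10), (5, 0), (2.5, 10)])
    def test_invalid_counts_rejected(self, n_plus, n):
        with pytest.raises(ValueError):
            qtlst_ee_pvalue(n_plus, n)


class TestExactEngine:
    def test_equal_effects_all_plus_is_one(self):
        """The headline degenerate case: zero variance leaves no power at all."""
        ds = oriented(np.full(10, 2.5))
        res = qtlst_exact(ds)
        assert res.p_value == 1.0
        assert not res.reject

    @pytest.mark.parametrize("magnitude", [1.0, 0.1, 1 / 3, 2.7e-3])
    @pytest.mark.parametrize("n_plus", [10, 9, 8, 6])
    def test_equal_effects_any_nplus_is_one(self, magnitude, n_plus):
        dirs = np.where(np.arange(10) < n_plus, 1, -1)
        ds = oriented(np.full(10, magnitude), dirs)
        assert qtlst_exact(ds).p_value == 1.0

    def test_hand_enumerable_three_locus_case(self):
        ds = oriented([1.0, 1.0, 4.0])
        res = qtlst_exact(ds)
        assert res.p_value == pytest.approx(19 / 25, abs=1e-14)
        assert res.event_probability == pytest.approx(25 / 216, abs=1e-14)

    def test_matches_brute_force_enumeration_small_n(self):
        """Exact engine equals (2n)^n brute-force enumeration to 1e-12."""
        rng = np.random.default_rng(3)
        for n in (2, 3, 4):
            for _ in range(4):
                mags = rng.gamma(1.0, 1.0, n)
                ds = orient_dataset(mags, rng.choice([-1, 1], n))
                r_half = signed_half_difference(ds)
                p_engine, event, _ = qtlst_conditional_tail(mags, ds.n_plus, r_half)
                p_brute, event_brute = brute_force_qtlst(mags, ds.n_plus, r_half)
                assert p_engine == pytest.approx(p_brute, abs=1e-12)
                assert event == pytest.approx(event_brute, abs=1e-12)

    def test_strata_sum_to_event_probability(self):
        rng = np.random.default_rng(4)
        mags = rng.gamma(1.0, 1.0, 10)
        ds = orient_dataset(mags, rng.choice([-1, 1], 10))
        res = qtlst_exact(ds)
        assert res.strata.sum() == pytest.approx(res.event_probability, abs=1e-12)
        assert np.all(res.strata >= 0)
        assert res.event_probability > (1.0 / 20.0) ** 10

    def test_pvalue_nonincreasing_in_nplus(self):
        """With magnitudes and R held fixed, the conditional tail shrinks."""
        rng = np.random.default_rng(9)
        mags = rng.gamma(0.5, 2.0, 10)
        r_half = 0.4 * mags.sum()
        pvals = [qtlst_conditional_tail(mags, k, r_half)[0] for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(pvals, pvals[1:]))

    def test_unoriented_dataset_rejected(self):
        from qtlsign import QTLDataset

        ds = QTLDataset(magnitudes=[1.0, 3.0], directions=[1, -1])
        with pytest.raises(ValueError):
            qtlst_exact(ds)

    def test_high_variance_all_plus_can_reject(self):
        # unequal magnitudes restore power: many resamples overshoot R
        ds = oriented([0.1] * 9 + [10.0])
        assert qtlst_exact(ds).p_value < 0.05


class TestMonteCarloEngine:
    def test_equal_effects_exact_even_at_tiny_M(self):
        ds = oriented(np.full(10, 0.7))
        res = qtlst_mc(ds, M=10, rng=np.random.default_rng(0))
        assert res.p_value == 1.0

    def test_matches_exact_engine_on_hand_case(self):
        ds = oriented([1.0, 1.0, 4.0])
        M = 100_000
        res = qtlst_mc(ds, M=M, rng=np.random.default_rng(1))
        se = np.sqrt(19 / 25 * 6 / 25 / M)
        assert abs(res.p_value - 19 / 25) < 3 * se

    def test_matches_exact_engine_on_random_dataset(self):
        rng = np.random.default_rng(14)
        mags = rng.gamma(1.0, 1.0, 10)
        ds = orient_dataset(mags, rng.choice([-1, 1], 10))
        exact = qtlst_exact(ds).p_value
        M = 100_000
        mc = qtlst_mc(ds, M=M, rng=np.random.default_rng(15)).p_value
        se = np.sqrt(max(exact * (1 - exact), 1e-4) / M)
        assert abs(mc - exact) < 3 * se

    def test_deterministic_given_seed(self):
        ds = oriented([0.3, 1.2, 2.0, 0.9])
        a = qtlst_mc(ds, M=5_000, rng=np.random.default_rng(7)).p_value
        b = qtlst_mc(ds, M=5_000, rng=np.random.default_rng(7)).p_value
        assert a == b

    def test_error_shrinks_with_replicates(self):
        """Consistency: the MC estimate converges to the exact value as M grows."""
        ds = oriented([0.5, 0.8, 1.1, 1.9, 0.2, 1.4, 0.7, 1.0, 0.6, 2.2])
        exact = qtlst_exact(ds).p_value
        errs = {}
        for M in (1_000, 10_000, 100_000):
            reps = [
                abs(qtlst_mc(ds, M=M, rng=np.random.default_rng(100 + r)).p_value - exact)
                for r in range(3)
            ]
            errs[M] = np.mean(reps)
        assert errs[100_000] < errs[1_000]

    def test_invalid_draw_count_rejected(self):
        with pytest.raises(ValueError):
            qtlst_mc(oriented([1.0, 2.0]), M=0)


class TestDispatchAndDecision:
    def test_auto_uses_exact_for_small_n(self):
        assert qtlst(oriented([1.0, 2.0, 3.0])).method == "QTLST-exact"

    def test_auto_uses_mc_for_large_n(self):
        rng = np.random.default_rng(21)
        ds = orient_dataset(rng.gamma(1, 1, 15), rng.choice([-1, 1], 15))
        res = qtlst(ds, rng=np.random.default_rng(22), M=2_000)
        assert res.method == "QTLST-MC"

    @pytest.mark.parametrize(
        "p, alpha, expect",
        [(0.021, 0.05, True), (0.11, 0.05, False), (1.0, 0.999, False)],
    )
    def test_rejection_rule(self, p, alpha, expect):
        res = qtlst_ee(oriented([1.0] * 10))
        res.p_value = p
        assert decide(res, alpha) is expect

    def test_invalid_alpha_rejected(self):
        res = qtlst_ee(oriented([1.0] * 10))
        with pytest.raises(ValueError):
            decide(res, 1.5)
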