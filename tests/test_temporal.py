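"""Gamma/MCCR, LTT series and envelopes, segment fits, sliding windows."""

import dendropy
import numpy as np
import pytest

from chronodiv.chronogram import BranchingTimes
from chronodiv.simulate import simulate_yule, yule_branching_times
from chronodiv.temporal import (
    LTTSeries,
    TABLE_PERIODS,
    gamma_stat,
    lineage_count_at,
    ltt_envelope,
    ltt_segment_fit,
    ltt_series,
    mccr_test,
    sliding_window_rates,
)


def _bt(ages, n=None):
    ages = np.asarray(ages, dtype=float)
    return BranchingTimes(ages, n or len(ages) + 1)


class TestGamma:
    def test_hand_computed_value(self):
        # unit intervals: T_2=2, T_3=5, T=9, numerator -1, denom 9*sqrt(1/24)
        assert gamma_stat(_bt([3, 2, 1])) == pytest.approx(-0.54433105, abs=1e-6)

    def test_scale_invariance(self):
        bt = yule_branching_times(40, 1.0, seed=3)
        for c in (0.01, 3.7, 1000.0):
            assert gamma_stat(bt.rescaled(c * bt.crown_age)) == pytest.approx(
                gamma_stat(bt), rel=1e-12
            )

    def test_matches_independent_implementation(self, yule_trees):
        for tree in yule_trees:
            dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
            expected = dendropy.calculate.treemeasure.pybus_harvey_gamma(dtree)
            assert gamma_stat(tree) == pytest.approx(expected, abs=1e-8)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            gamma_stat(_bt([2.0, 1.0]))


class TestMCCR:
    def test_null_median_gives_half_p(self):
        res = mccr_test(0.0, 100, 100, reps=1000, seed=1)
        med = res.null_quantiles["50"]
        res2 = mccr_test(med, 100, 100, reps=1000, seed=1)
        assert res2.p_value == pytest.approx(0.5, abs=0.05)

    def test_strong_slowdown_significant(self):
        res = mccr_test(-3.0, 100, 100, reps=500, seed=2)
        assert res.p_value < 0.05

    def test_p_monotone_in_gamma(self):
        grid = np.linspace(-3, 3, 9)
        ps = [mccr_test(g, 74, 100, reps=300, seed=5).p_value for g in grid]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_no_prune_equals_full_sampling(self):
        a = mccr_test(0.3, 80, 80, reps=300, prune=True, seed=7)
        b = mccr_test(0.3, 80, 80, reps=300, prune=False, seed=7)
        assert a.null_quantiles == b.null_quantiles
        assert a.p_value == b.p_value

    def test_pruned_null_shifts_negative(self):
        """Incomplete sampling pushes the gamma null toward slowdown values."""
        pruned = mccr_test(0.0, 50, 100, reps=300, seed=9)
        full = mccr_test(0.0, 100, 100, reps=300, seed=9)
        assert pruned.null_quantiles["50"] < full.null_quantiles["50"]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mccr_test(0.0, 101, 100, reps=200, seed=0)
        with pytest.raises(ValueError):
            mccr_test(0.0, 50, 100, reps=10, seed=0)


class TestLTT:
    def test_series_counts(self):
        s = ltt_series(_bt([3, 2.5, 1]))
        assert s.ages.tolist() == [3, 2.5, 1]
        assert s.counts.tolist() == [2, 3, 4]

    def test_final_count_is_n_tips(self, yule_trees):
        for t in yule_trees:
            s = ltt_series(t.branching_times())
            assert s.counts[-1] == t.n_tips
            assert np.all(np.diff(s.counts) == 1)

    def test_count_edge_conventions(self):
        bt = _bt([3, 2, 1])
        assert lineage_count_at(bt, 3.0) == 2  # branching at the edge counts
        assert lineage_count_at(bt, 3.5) == 1
        assert lineage_count_at(bt, 0.0) == 4

    def test_envelope_single_rep_collapses(self):
        t = simulate_yule(20, 1.0, seed=4)
        env = ltt_envelope(t, reps=1, seed=0)
        assert np.allclose(env.band95[0], env.band95[1])

    def test_envelope_widens_toward_present(self):
        t = simulate_yule(40, 1.0, seed=5)
        env = ltt_envelope(t, reps=200, seed=1)
        width = env.band95[1] - env.band95[0]
        assert width[-10:].mean() >= 0  # present end defined
        assert width[len(width) // 2] > width[2]  # wider than near the crown

    def test_envelope_coverage_under_null(self):
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(20):
            t = simulate_yule(40, 1.0, seed=int(rng.integers(2**31)))
            env = ltt_envelope(t, reps=150, seed=int(rng.integers(2**31)))
            fracs.append(env.excluded.mean())
        assert np.mean(fracs) < 0.10


class TestSegments:
    def test_exact_exponential_recovered(self):
        r, T = 0.31, 40.0
        counts = np.arange(2, 60)
        ages = T - np.log(counts / 2.0) / r  # N(t) = 2 exp(r (T - age))
        series = LTTSeries(ages, counts, 60)
        fit = ltt_segment_fit(series, periods=[(T, 0)], scale="log")[0]
        assert fit.slope == pytest.approx(r, abs=1e-6)

    def test_constant_count_zero_slope(self):
        series = LTTSeries(np.array([5.0, 3.0]), np.array([4, 4]), 4)
        fit = ltt_segment_fit(series, periods=[(6, 2)], scale="raw")[0]
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_sparse_period_flagged_not_dropped(self):
        series = ltt_series(_bt([30, 20, 10]))
        fits = ltt_segment_fit(series, periods=[(50, 40), (35, 5)])
        assert len(fits) == 2
        assert not fits[0].ok and np.isnan(fits[0].slope)
        assert fits[1].ok

    def test_default_periods(self):
        assert TABLE_PERIODS == [(50, 30), (30, 20), (20, 15), (15, 10), (10, 5), (5, 0)]


class TestSlidingWindows:
    def test_direct_formula(self):
        # Nb=10, Nt=20, width 5 -> ln(2)/5
        bt = yule_branching_times(40, 1.0, seed=13)
        win = sliding_window_rates(bt, width=1.0, step=1.0, t_old=bt.crown_age, t_young=0)
        for w in win:
            if w.valid:
                assert w.rate == pytest.approx(-np.log(w.nb / w.nt) / 1.0, rel=1e-12)
        assert -np.log(10 / 20) / 5 == pytest.approx(0.138629, abs=1e-5)

    def test_equal_counts_zero_rate(self):
        bt = _bt([10.0, 9.0, 8.0])
        w = sliding_window_rates(bt, width=2.0, step=2.0, t_old=8.0, t_young=2.0)
        assert all(rec.nb == rec.nt and rec.rate == 0.0 for rec in w)

    def test_windows_outside_span_flagged(self):
        bt = _bt([10.0, 5.0, 1.0])
        w = sliding_window_rates(bt, width=5.0, step=1.0, t_old=20.0, t_young=0.0)
        assert any(not rec.valid for rec in w)
        assert all(rec.valid for rec in w if rec.start <= 10.0)

    def test_estimates_pure_birth_rate(self):
        """Window rates scatter around the true speciation rate."""
        lam = 0.4
        rng = np.random.default_rng(17)
        rates = []
        for _ in range(200):
            bt = yule_branching_times(60, lam, seed=int(rng.integers(2**31)))
            win = sliding_window_rates(
                bt, width=bt.crown_age / 5, step=bt.crown_age / 5,
                t_old=bt.crown_age, t_young=0,
            )
            rates.extend(w.rate for w in win if w.valid)
        assert np.median(rates) == pytest.approx(lam, rel=0.20)

    def test_step_invariance_of_edge_rates(self):
        bt = yule_branching_times(50, 1.0, seed=19)
        w1 = sliding_window_rates(bt, width=1.0, step=0.5, t_old=4.0, t_young=0)
        w2 = sliding_window_rates(bt, width=1.0, step=1.0, t_old=4.0, t_young=0)
        r1 = {w.start: w.rate for w in w1 if w.valid}
        r2 = {w.start: w.rate for w in w2 if w.valid}
        for k in r2:
            assert r1[k] == r2[k]

    def test_parameter_validation(self):
        bt = _bt([3, 2, 1])
        with pytest.raises(ValueError):
            sliding_window_rates(bt, width=0)
        with pytest.raises(ValueError):
            sliding_window_rates(bt, t_old=1.0, t_young=2.0)
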