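"""Diversification model fits: closed forms, nesting, reductions, dAIC."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from chronodiv.chronogram import BranchingTimes
from chronodiv.models import (
    daic_critical_value,
    ddl_loglik,
    ddx_loglik,
    delta_aic_rc,
    fit_bd,
    fit_constant_models,
    fit_ddl,
    fit_ddx,
    fit_variable_models,
    fit_yule,
    fit_yule_shift,
    yule_loglik,
)
from chronodiv.simulate import SimParams, simulate_bd_reconstructed, yule_branching_times


def _bt(ages, n=None):
    return BranchingTimes(np.asarray(ages, dtype=float), n or len(ages) + 1)


class TestYule:
    def test_closed_form_example(self):
        fit = fit_yule(_bt([3, 2, 1]))
        assert fit.params["lambda"] == pytest.approx(2 / 9)

    def test_closed_form_equals_numeric_optimum(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            bt = yule_branching_times(int(rng.integers(5, 60)), 1.0, rng)
            fit = fit_yule(bt)
            res = minimize_scalar(
                lambda l: -yule_loglik(bt, l),
                bounds=(1e-8, 50.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            # parabolic polish: Brent's floor is ~sqrt(eps)*x, tighter is needed
            x0 = float(res.x)
            h = 1e-4 * x0
            fm, f0, fp = (yule_loglik(bt, x0 + d) for d in (-h, 0.0, h))
            x_num = x0 + 0.5 * h * (fm - fp) / (fm - 2 * f0 + fp)
            assert fit.params["lambda"] == pytest.approx(x_num, abs=1e-8)
            assert fit.log_likelihood >= -float(res.fun) - 1e-10

    def test_rate_recovery_large_trees(self):
        rng = np.random.default_rng(31)
        lams = [
            fit_yule(yule_branching_times(500, 0.1, rng)).params["lambda"]
            for _ in range(60)
        ]
        assert np.median(lams) == pytest.approx(0.1, rel=0.05)


class TestNesting:
    def test_bd_never_below_yule(self, yule_trees):
        for i, t in enumerate(yule_trees):
            y, bd = fit_constant_models(t.branching_times(), seed=i)
            assert bd.log_likelihood >= y.log_likelihood - 1e-9

    def test_variable_model_nesting(self, yule_trees):
        for t in yule_trees:
            bt = t.branching_times()
            y = fit_yule(bt)
            y2, y3, ddl, ddx = fit_variable_models(bt)
            assert y2.log_likelihood >= y.log_likelihood - 1e-9
            assert y3.log_likelihood >= y2.log_likelihood - 1e-9
            assert ddx.log_likelihood >= y.log_likelihood - 1e-9
            assert ddl.log_likelihood >= y.log_likelihood - 1e-6

    def test_bd_fit_on_extinction_trees(self):
        t = simulate_bd_reconstructed(
            SimParams(n_tips=60, lam=(1.0,), mu=(0.6,), seed=37)
        )
        y, bd = fit_constant_models(t.branching_times(), seed=0)
        assert bd.log_likelihood >= y.log_likelihood - 1e-9
        assert bd.params["mu"] >= 0


class TestReductions:
    def test_ddx_zero_exponent_is_yule(self, yule_trees):
        for t in yule_trees:
            bt = t.branching_times()
            lam = fit_yule(bt).params["lambda"]
            assert ddx_loglik(bt, lam, 0.0) == pytest.approx(
                yule_loglik(bt, lam), abs=1e-9
            )

    def test_ddl_infinite_k_is_yule(self, yule_trees):
        for t in yule_trees:
            bt = t.branching_times()
            lam = fit_yule(bt).params["lambda"]
            assert ddl_loglik(bt, lam, np.inf) == pytest.approx(
                yule_loglik(bt, lam), abs=1e-9
            )
            assert ddl_loglik(bt, lam, 1e9) == pytest.approx(
                yule_loglik(bt, lam), abs=1e-4
            )

    def test_boundary_flags_reported(self):
        # on a clean pure-birth tree DDL usually collapses to the Yule boundary
        bt = yule_branching_times(40, 1.0, seed=41)
        ddl = fit_ddl(bt)
        ddx = fit_ddx(bt)
        if "K-at-infinity" in ddl.flags:
            assert ddl.log_likelihood == pytest.approx(
                fit_yule(bt).log_likelihood, abs=1e-9
            )
        if "x-at-zero" in ddx.flags:
            assert ddx.params["x"] == 0.0


class TestTimeRescaling:
    def test_rates_scale_and_daic_invariant(self):
        bt = yule_branching_times(50, 1.0, seed=43)
        c = 7.3
        bts = BranchingTimes(bt.ages * c, bt.n_tips)
        y1, y2 = fit_yule(bt), fit_yule(bts)
        assert y2.params["lambda"] == pytest.approx(y1.params["lambda"] / c, rel=1e-9)
        d1 = delta_aic_rc(bt, seed=0).daic
        d2 = delta_aic_rc(bts, seed=0).daic
        assert d2 == pytest.approx(d1, abs=0.05)


class TestYuleShift:
    def test_breakpoint_recovery_strong_shift(self):
        hits = total = 0
        for s in range(30):
            t = simulate_bd_reconstructed(
                SimParams(
                    n_tips=20, lam=(0.05, 0.5), mu=(0.0, 0.0),
                    shift_times=(5.0,), crown_age=10.0, seed=s,
                )
            )
            total += 1
            bp = fit_yule_shift(t.branching_times(), 1).params["breakpoints"][0]
            depth = t.crown_age
            hits += depth / 3 <= bp <= 2 * depth / 3
        assert hits / total >= 0.7

    def test_requires_enough_events(self):
        with pytest.raises(ValueError):
            fit_yule_shift(_bt([3, 2, 1]), 1)


class TestDAIC:
    def test_orientation_more_rv_models_increase_daic(self, yule_trees):
        bt = yule_trees[1].branching_times()
        res = delta_aic_rc(bt, seed=0)
        rc_best = min(m.aic for m in res.all_fits if m.name in ("yule", "bd"))
        only_dd = rc_best - min(
            m.aic for m in res.all_fits if m.name in ("ddl", "ddx")
        )
        assert res.daic >= only_dd - 1e-12

    def test_null_median_small(self):
        rng = np.random.default_rng(47)
        ds = [
            delta_aic_rc(
                yule_branching_times(40, 1.0, rng), seed=int(rng.integers(2**31))
            ).daic
            for _ in range(60)
        ]
        assert np.median(ds) <= 2.0

    def test_power_on_strong_two_regime_trees(self):
        wins = total = 0
        for s in range(25):
            t = simulate_bd_reconstructed(
                SimParams(
                    n_tips=40, lam=(0.06, 0.6), mu=(0.0, 0.0),
                    shift_times=(5.0,), crown_age=10.0, seed=100 + s,
                )
            )
            total += 1
            wins += delta_aic_rc(t.branching_times(), seed=s).daic > 4.0
        assert wins / total >= 0.8

    def test_critical_value_quantile_monotone(self):
        rng = np.random.default_rng(53)
        c50, sample = daic_critical_value(20, reps=60, q=0.50, seed=int(rng.integers(2**31)))
        c95 = float(np.quantile(sample, 0.95))
        assert c50 < c95
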