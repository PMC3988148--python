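"""Simulator distributional properties and seed-determinism contracts."""

import numpy as np
import pytest
from scipy import stats

from chronodiv.chronogram import parse_chronogram
from chronodiv.simulate import (
    SimParams,
    make_nerita_like,
    simulate_bd_conditioned,
    simulate_bd_reconstructed,
    simulate_beta_splitting_topology,
    simulate_yule,
    yule_branching_times,
)
from chronodiv.temporal import gamma_stat


def test_yule_two_tips():
    t = simulate_yule(2, 1.0, seed=0)
    assert t.n_tips == 2
    assert len(t.branching_times().ages) == 1


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: simulate_yule(20, 1.0, seed=s),
        lambda s: simulate_bd_reconstructed(
            SimParams(n_tips=20, lam=(1.0,), mu=(0.3,), seed=s)
        ),
        lambda s: simulate_beta_splitting_topology(20, -1.0, seed=s),
        lambda s: make_nerita_like(seed=s, n_tips=30),
    ],
)
def test_seed_determinism(factory):
    assert factory(42).to_newick() == factory(42).to_newick()
    assert factory(42).to_newick() != factory(43).to_newick()


def test_simulated_trees_are_valid_chronograms():
    for seed in range(5):
        t = simulate_yule(30, 1.0, seed=seed)
        # re-validation through the parser is the strictest check
        t2 = parse_chronogram(t.to_newick())
        assert t2.n_tips == 30


def test_pure_birth_gamma_null_moments():
    """gamma is asymptotically standard normal under pure birth at n = 100."""
    rng = np.random.default_rng(1)
    g = np.array([gamma_stat(yule_branching_times(100, 1.0, rng)) for _ in range(1000)])
    assert abs(g.mean()) < 3.0 / np.sqrt(1000) * np.sqrt(1.2)  # sd slightly > 1 at finite n
    assert 0.8 < g.var() < 1.2


def test_doubling_lambda_halves_crown_age():
    rng = np.random.default_rng(2)
    m1 = np.mean([yule_branching_times(50, 1.0, rng).crown_age for _ in range(1000)])
    m2 = np.mean([yule_branching_times(50, 2.0, rng).crown_age for _ in range(1000)])
    assert m1 / m2 == pytest.approx(2.0, rel=0.10)


def test_bd_reduces_to_yule_without_extinction():
    """mu = 0, rho = 1 forward birth-death is distributionally pure birth."""
    rng = np.random.default_rng(3)
    crowns_bd = [
        simulate_bd_reconstructed(
            SimParams(n_tips=20, lam=(1.0,), mu=(0.0,), seed=int(rng.integers(2**31)))
        ).crown_age
        for _ in range(300)
    ]
    crowns_y = [
        simulate_yule(20, 1.0, seed=int(rng.integers(2**31))).crown_age
        for _ in range(300)
    ]
    assert stats.ks_2samp(crowns_bd, crowns_y).pvalue > 0.01


def test_rho_subsampling_tip_count():
    t = simulate_bd_reconstructed(
        SimParams(n_tips=200, lam=(1.0,), mu=(0.0,), rho=0.5, seed=4)
    )
    assert t.n_tips == 100


def test_near_zero_netdiv_plateaus_ltt():
    """After a shift to near-zero net diversification the LTT flattens."""
    growth = []
    for s in range(100):
        t = simulate_bd_reconstructed(
            SimParams(
                n_tips=30,
                lam=(0.02, 0.5),
                mu=(0.019, 0.0),
                shift_times=(4.0,),
                crown_age=12.0,
                seed=s,
            )
        )
        bt = t.branching_times()
        n_at_shift = 1 + int(np.sum(bt.ages >= 4.0))
        growth.append(30 / n_at_shift)
    assert np.mean(growth) < 1.2


def test_erm_root_split_probability():
    """Under beta = 0 a 4-tip root splits (2,2) w.p. 1/3, (1,3) w.p. 2/3."""
    hits = 0
    for s in range(10000):
        t = simulate_beta_splitting_topology(4, 0.0, seed=s)
        root = next(r for r in t.split_records() if r.size == 4)
        hits += {root.left_tips, root.right_tips} == {2}
    assert hits / 10000 == pytest.approx(1 / 3, abs=0.02)


def test_large_beta_balances_root():
    def root_balanced_freq(beta, reps=300):
        hits = 0
        for s in range(reps):
            t = simulate_beta_splitting_topology(16, beta, seed=s)
            root = next(r for r in t.split_records() if r.size == 16)
            hits += root.left_tips == 8
        return hits / reps

    assert root_balanced_freq(100.0) > root_balanced_freq(0.0)


def test_two_tip_topology_deterministic():
    t = simulate_beta_splitting_topology(2, 0.0, seed=9)
    assert t.n_tips == 2


def test_nerita_like_scenario_shape():
    t = make_nerita_like(seed=5)
    assert t.n_tips == 74
    assert t.crown_age == pytest.approx(55.7, abs=1e-6)
    # the slowdown leaves few nodes younger than the 24 Ma shift
    bt = t.branching_times()
    assert np.sum(bt.ages < 24.0) < np.sum(bt.ages >= 24.0)


def _descendant_count(T, lam_iv, mu_iv, shifts, rho, rng):
    """Brute-force: one lineage born at backward age T; sampled descendants."""
    bounds = sorted(shifts)

    def rates(tau):
        age = T - tau
        i = int(np.searchsorted(bounds, age, side="left"))
        return lam_iv[i], mu_iv[i]

    n, tau = 1, 0.0
    while n > 0:
        lam, mu = rates(tau)
        dt = rng.exponential(1 / (n * (lam + mu)))
        nxt = min([T - b for b in bounds if T - b > tau] + [T])
        if tau + dt >= nxt:
            if nxt >= T:
                break
            tau = nxt  # rate shift: reposition and redraw (memoryless)
            continue
        tau += dt
        if rng.random() < lam / (lam + mu):
            n += 1
        else:
            n -= 1
        if n > 5000:
            break
    return rng.binomial(n, rho) if n else 0


def test_bd_kernel_matches_direct_simulation():
    """Closed-form p0/p1 across a rate shift equal brute-force probabilities.

    These kernels drive both the piecewise likelihood and the conditional
    tree sampler, so they get their own independent stochastic oracle.
    """
    from chronodiv._bd_math import PiecewiseBD

    T, lam_iv, mu_iv, shifts, rho = 3.0, (0.6, 0.3), (0.2, 0.5), (1.2,), 0.7
    rng = np.random.default_rng(2)
    reps = 15000
    d = np.array(
        [_descendant_count(T, lam_iv, mu_iv, shifts, rho, rng) for _ in range(reps)]
    )
    proc = PiecewiseBD(lam_iv, mu_iv, shifts, rho)
    p0, lp1 = proc.p0_logp1(np.array([T]))
    se0 = np.sqrt(p0[0] * (1 - p0[0]) / reps)
    p1 = np.exp(lp1[0])
    se1 = np.sqrt(p1 * (1 - p1) / reps)
    assert np.mean(d == 0) == pytest.approx(p0[0], abs=4 * se0)
    assert np.mean(d == 1) == pytest.approx(p1, abs=4 * se1)


def test_conditional_sampler_node_age_law_pure_birth():
    """At mu = 0, rho = 1 the conditional node ages are truncated-exponential
    toward the present (the classical pure-birth result)."""
    rng = np.random.default_rng(8)
    ages = np.concatenate(
        [
            simulate_bd_conditioned(40, 5.0, (0.9,), (0.0,), seed=int(rng.integers(2**31)))
            .branching_times()
            .ages[1:]
            for _ in range(100)
        ]
    )
    lam, T = 0.9, 5.0
    cdf = lambda t: (1 - np.exp(-lam * t)) / (1 - np.exp(-lam * T))
    assert stats.kstest(ages, cdf).pvalue > 0.005


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(n_tips=1)
    with pytest.raises(ValueError):
        SimParams(n_tips=10, lam=(0.0,))
    with pytest.raises(ValueError):
        SimParams(n_tips=10, rho=0.0)
    with pytest.raises(ValueError):
        SimParams(n_tips=10, lam=(1.0, 2.0), mu=(0.0, 0.0))  # shifts missing
    with pytest.raises(ValueError):
        simulate_beta_splitting_topology(10, -2.5, seed=0)
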