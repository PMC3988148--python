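"""Piecewise-constant birth-death-sampling likelihood and stepwise shift search.

The model: a reconstructed phylogeny generated by a birth-death process whose
speciation/extinction rates (lambda_i, mu_i) are constant within intervals
delimited by shift times (backward ages, present-most interval first), with
each extant lineage sampled at the present with probability rho.  Intervals
are parameterized by turnover eps_i = mu_i/lambda_i and net diversification
r_i = lambda_i - mu_i, the quantities a shift table reports.

The search procedure mirrors the grid-based stepwise protocol: candidate
shift times live on a fixed grid (default 34 to 3 Ma, 1 Ma spacing); at each
round the single best new shift is added with previous shifts held fixed,
and a likelihood-ratio test compares the m-shift model to the (m-1)-shift
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._bd_math import PiecewiseBD
from .chronogram import BranchingTimes, Chronogram

__all__ = [
    "ShiftFit",
    "piecewise_bd_loglik",
    "fit_piecewise_bd",
    "stepwise_shift_search",
    "LRT_DF_PER_SHIFT",
]

#: degrees of freedom charged per added shift in the LRT: the shift time
#: plus one (turnover, net-diversification) pair.
LRT_DF_PER_SHIFT = 3

_RATE_LO, _RATE_HI = 1e-6, 20.0


def _rates_from_tu_div(turnover, netdiv):
    """(turnover, netdiv) -> (lambda, mu); requires lambda > 0, mu >= 0."""
    eps = np.atleast_1d(np.asarray(turnover, dtype=float))
    r = np.atleast_1d(np.asarray(netdiv, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = r / (1.0 - eps)
    lam = np.where(eps == 1.0, np.inf, lam)
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError(
            "invalid (turnover, netdiv): need netdiv/(1 - turnover) > 0 "
            "(turnover > 1 encodes a decline regime with netdiv < 0)"
        )
    mu = eps * lam
    if np.any(mu < 0):
        raise ValueError("negative extinction rate implied")
    return lam, mu


def piecewise_bd_loglik(bt, shift_times, turnover, netdiv, rho: float = 1.0) -> float:
    """Log-likelihood of branching times under the piecewise BD-sampling model.

    Conditioned on the crown age and on both crown lineages surviving to
    sampling:

        l = sum_{i>=2} [ln lambda(x_i) + ln p1(x_i)]
            + 2 ln p1(x_1) - 2 ln(1 - p0(x_1))

    where x_1 >= x_2 >= ... are the node ages, lambda(t) the rate in the
    interval containing t, and p0/p1 the extinction/one-sampled-descendant
    probabilities propagated across shift boundaries by continuity (all in
    log space; underflow cannot occur silently).  With no shifts, rho = 1
    and turnover 0 this reduces exactly to the Yule likelihood.
    """
    bt = bt.branching_times() if isinstance(bt, Chronogram) else bt
    lam, mu = _rates_from_tu_div(turnover, netdiv)
    proc = PiecewiseBD(lam, mu, shift_times, rho)
    x = bt.ages
    p0_crown, logp1_crown = proc.p0_logp1(np.array([x[0]]))
    _, logp1 = proc.p0_logp1(x[1:])
    ll = (
        float(np.sum(np.log(proc.lam_at(x[1:])) + logp1))
        + 2.0 * float(logp1_crown[0])
        - 2.0 * float(np.log1p(-p0_crown[0]))
    )
    return ll


@dataclass(frozen=True)
class ShiftFit:
    """One row of a shift table: an m-shift piecewise BD-sampling fit."""

    n_shifts: int
    shift_times: tuple          # ascending ages (Ma); T1, T2, ...
    turnover: tuple             # eps_i per interval, present-most first
    netdiv: tuple               # r_i per interval, present-most first
    rho: float
    log_likelihood: float
    p_vs_one_fewer: float | None
    converged: bool = True
    flags: tuple = ()

    @property
    def lam(self):
        return tuple(np.asarray(self.netdiv) / (1.0 - np.asarray(self.turnover)))

    @property
    def mu(self):
        return tuple(np.asarray(self.turnover) * np.asarray(self.lam))


def _loglik_rates(bt, shift_times, lam, mu, rho):
    try:
        proc = PiecewiseBD(lam, mu, shift_times, rho)
    except ValueError:
        return -np.inf
    x = bt.ages
    p0, lp1 = proc.p0_logp1(x)
    if p0[0] >= 1.0 - 1e-12:
        return -np.inf
    return (
        float(np.sum(np.log(proc.lam_at(x[1:])) + lp1[1:]))
        + 2.0 * float(lp1[0])
        - 2.0 * float(np.log1p(-p0[0]))
    )


def fit_piecewise_bd(
    bt,
    shift_times=(),
    rho: float = 1.0,
    n_starts: int = 5,
    seed=None,
    p_vs_one_fewer=None,
    warm=None,
) -> ShiftFit:
    """Maximize the piecewise likelihood over per-interval (lambda_i, mu_i).

    Rates are optimized on a log-lambda scale with mu bounded at zero; five
    seeded starts (one at the Yule estimate with low extinction, the rest
    log-uniform) guard against the multimodality the profile develops when
    intervals hold few events.  Reported per-interval values are re-expressed
    as (turnover, net diversification).
    """
    bt = bt.branching_times() if isinstance(bt, Chronogram) else bt
    shift_times = tuple(sorted(float(s) for s in shift_times))
    if shift_times and shift_times[-1] >= bt.crown_age:
        raise ValueError("shift times must be younger than the crown age")
    k = len(shift_times) + 1
    rng = np.random.default_rng(seed)
    n = bt.n_tips
    lam_yule = (n - 2) / np.sum(np.arange(2, n + 1) * -np.diff(np.append(bt.ages, 0.0)))

    def nll(theta):
        lam = np.exp(np.clip(theta[:k], -30, 10))
        mu = lam * 2.0 * _expit(theta[k:])  # eps in (0, 2): allows decline regimes
        ll = _loglik_rates(bt, shift_times, lam, mu, rho)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = [np.concatenate([np.full(k, np.log(max(lam_yule, _RATE_LO))), np.full(k, -3.0)])]
    if warm is not None:
        starts.insert(0, np.asarray(warm, dtype=float))
    while len(starts) < n_starts:
        starts.append(
            np.concatenate(
                [
                    np.log(lam_yule) + rng.uniform(-2, 2, size=k),
                    rng.uniform(-4, 3, size=k),
                ]
            )
        )
    best = None
    ok = False
    for x0 in starts[:n_starts]:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 1500, "xatol": 1e-5, "fatol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    lam = np.exp(best.x[:k])
    mu = lam * 2.0 * _expit(best.x[k:])
    eps = mu / lam
    r = lam - mu
    flags = []
    if np.any(eps > 1.0):
        flags.append("decline-regime")  # turnover > 1, net diversification < 0
    return ShiftFit(
        n_shifts=len(shift_times),
        shift_times=shift_times,
        turnover=tuple(float(e) for e in eps),
        netdiv=tuple(float(v) for v in r),
        rho=float(rho),
        log_likelihood=-float(best.fun),
        p_vs_one_fewer=p_vs_one_fewer,
        converged=ok,
        flags=tuple(flags),
    )


def _expit(x):
    from scipy.special import expit

    return expit(x)


def _warm_theta(lam, mu, insert_at=None):
    """Optimizer vector from rates, optionally duplicating one interval."""
    lam = list(lam)
    mu = list(mu)
    if insert_at is not None:
        lam.insert(insert_at, lam[insert_at])
        mu.insert(insert_at, mu[insert_at])
    lam = np.asarray(lam)
    eps = np.clip(np.asarray(mu) / lam / 2.0, 1e-6, 1 - 1e-6)
    return np.concatenate([np.log(np.clip(lam, _RATE_LO, None)), np.log(eps / (1 - eps))])


def stepwise_shift_search(
    bt,
    t_min: float = 3.0,
    t_max: float = 34.0,
    grid: float = 1.0,
    rho: float = 1.0,
    max_shifts: int = 2,
    n_starts: int = 5,
    seed=None,
) -> list[ShiftFit]:
    """Grid-based stepwise search for diversification-rate shifts.

    Fits the 0-shift model, then for m = 1..max_shifts tries every grid time
    in [t_min, t_max] (spacing ``grid``, previously accepted shifts held
    fixed) as the next shift, keeping the candidate with the highest
    maximized likelihood.  Each row carries the LRT p-value against the
    model with one fewer shift (chi-squared reference with
    :data:`LRT_DF_PER_SHIFT` degrees of freedom per added shift).  Shift
    times stay on the grid; no continuous refinement is applied.
    """
    bt = bt.branching_times() if isinstance(bt, Chronogram) else bt
    if grid <= 0 or t_max <= t_min:
        raise ValueError("need grid > 0 and t_max > t_min")
    candidates = np.arange(t_min, t_max + grid / 2, grid)
    candidates = candidates[candidates < bt.crown_age * (1 - 1e-9)]
    if len(candidates) < 2:
        raise ValueError("grid must cover at least 2 candidate times inside the tree span")
    rng = np.random.default_rng(seed)
    fits = [fit_piecewise_bd(bt, (), rho, n_starts, rng.integers(2**31))]
    fixed: list[float] = []
    for _ in range(max_shifts):
        # cheap scan: warm start from the current fit (split interval's rates
        # duplicated) plus one cold start per candidate; the leaders are then
        # polished with the full multi-start budget
        prev = fits[-1]
        scan = []
        n_failed = 0
        for t in candidates:
            if any(abs(t - f) < 1e-9 for f in fixed):
                continue
            times = tuple(sorted(fixed + [float(t)]))
            j = int(np.searchsorted(list(prev.shift_times), t))
            warm = _warm_theta(prev.lam, prev.mu, insert_at=j)
            try:
                fit = fit_piecewise_bd(
                    bt, times, rho, 2, rng.integers(2**31), warm=warm
                )
            except (ValueError, FloatingPointError):
                n_failed += 1
                continue
            scan.append(fit)
        if not scan:
            raise RuntimeError(f"all {n_failed} shift candidates failed to fit")
        scan.sort(key=lambda f: -f.log_likelihood)
        best = scan[0]
        for cand_fit in scan[:3]:
            fit = fit_piecewise_bd(
                bt,
                cand_fit.shift_times,
                rho,
                n_starts,
                rng.integers(2**31),
                warm=_warm_theta(cand_fit.lam, cand_fit.mu),
            )
            if fit.log_likelihood > best.log_likelihood:
                best = fit
        prev = fits[-1]
        lr = 2.0 * max(0.0, best.log_likelihood - prev.log_likelihood)
        p = float(stats.chi2.sf(lr, LRT_DF_PER_SHIFT))
        best = ShiftFit(
            best.n_shifts,
            best.shift_times,
            best.turnover,
            best.netdiv,
            best.rho,
            best.log_likelihood,
            p,
            best.converged,
            best.flags,
        )
        fits.append(best)
        fixed = sorted(set(best.shift_times))
    return fits
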