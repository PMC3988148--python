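"""Piecewise-constant birth-death-sampling probability kernels.

Backward time t runs from the present (t = 0) into the past.  The process
has speciation rate lambda_i and extinction rate mu_i on interval i, where
interval 0 is [0, s_1), interval 1 is [s_1, s_2), ... for shift times
0 < s_1 < ... < s_m, and each extant lineage is sampled at the present with
probability rho.

Two functions of a lineage alive at time t drive everything:

* ``p0(t)`` — probability it leaves no sampled descendant at the present;
* ``p1(t)`` — probability it leaves exactly one sampled descendant lineage
  (equivalently the density factor of a reconstructed-tree branch).

Both satisfy Riccati/linear ODEs with the closed-form per-interval solutions
implemented below; across shift boundaries they propagate by continuity.
``p1`` is handled in log space throughout — for old lineages it underflows
long before the likelihood does.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PiecewiseBD"]

_RTOL_CRITICAL = 1e-9  # |lambda - mu| below this uses the critical-process limit


def _step(lam, mu, tau, p0_init, logp1_init):
    """Propagate (p0, log p1) forward by tau within one constant-rate interval."""
    tau = np.asarray(tau, dtype=float)
    r = lam - mu
    if abs(r) < _RTOL_CRITICAL * max(lam, 1.0):
        # critical process: dp/dtau = lam (p-1)^2
        u0 = 1.0 - p0_init
        denom = 1.0 + lam * u0 * tau
        p0 = 1.0 - u0 / denom
        logp1 = logp1_init - 2.0 * np.log(denom)
        return p0, logp1
    a = mu / lam
    if abs(p0_init - a) < 1e-14:
        # starting at the mu/lam equilibrium: p0 stays put, p1 decays at rate r
        p0 = np.full_like(tau, p0_init, dtype=float)
        return p0, logp1_init - r * tau
    # (p-1)/(p-a) = B with B = B0 * e^{r tau}
    b0 = (p0_init - 1.0) / (p0_init - a)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        B = b0 * np.exp(r * tau)
        p0 = (1.0 - a * B) / (1.0 - B)
        # p1(tau) = p1(0) e^{r tau} ((p0(tau)-a)/(p0(0)-a))^2
        logp1 = (
            logp1_init
            + r * tau
            + 2.0 * (np.log(np.abs(p0 - a)) - np.log(np.abs(p0_init - a)))
        )
    return p0, logp1


class PiecewiseBD:
    """Closed-form p0 / log p1 evaluator for a piecewise birth-death-sampling process.

    Parameters
    ----------
    lam, mu : array-like, one value per interval (present-most first)
    shift_times : array-like, strictly increasing ages (Ma); may be empty
    rho : sampling fraction at the present, in (0, 1]
    """

    def __init__(self, lam, mu, shift_times=(), rho: float = 1.0):
        self.lam = np.atleast_1d(np.asarray(lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self.shift_times = np.atleast_1d(np.asarray(shift_times, dtype=float))
        self.rho = float(rho)
        m = len(self.shift_times)
        if len(self.lam) != m + 1 or len(self.mu) != m + 1:
            raise ValueError("need len(shift_times) + 1 rate intervals")
        if np.any(self.lam <= 0) or np.any(self.mu < 0):
            raise ValueError("require lambda > 0 and mu >= 0 in every interval")
        if m and (np.any(np.diff(self.shift_times) <= 0) or self.shift_times[0] <= 0):
            raise ValueError("shift times must be strictly increasing and positive")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        # boundary states at each shift time, propagated from the present
        self._b_p0 = np.empty(m + 1)
        self._b_logp1 = np.empty(m + 1)
        self._b_p0[0] = 1.0 - self.rho
        self._b_logp1[0] = np.log(self.rho)
        lower = 0.0
        for i in range(m):
            p0, lp1 = _step(
                self.lam[i],
                self.mu[i],
                self.shift_times[i] - lower,
                self._b_p0[i],
                self._b_logp1[i],
            )
            self._b_p0[i + 1] = p0
            self._b_logp1[i + 1] = lp1
            lower = self.shift_times[i]
        self._lower = np.concatenate([[0.0], self.shift_times])

    def interval_of(self, t):
        """Index of the rate interval containing backward age t (right-open)."""
        return np.searchsorted(self.shift_times, t, side="right")

    def p0_logp1(self, t):
        """Vectorized (p0(t), log p1(t)) for backward ages t >= 0."""
        t = np.asarray(t, dtype=float)
        idx = self.interval_of(t)
        p0 = np.empty(t.shape)
        lp1 = np.empty(t.shape)
        for i in range(len(self.lam)):
            sel = idx == i
            if not sel.any():
                continue
            p0[sel], lp1[sel] = _step(
                self.lam[i],
                self.mu[i],
                t[sel] - self._lower[i],
                self._b_p0[i],
                self._b_logp1[i],
            )
        return p0, lp1

    def p0(self, t):
        return self.p0_logp1(t)[0]

    def log_p1(self, t):
        return self.p0_logp1(t)[1]

    def lam_at(self, t):
        """Speciation rate at backward age t."""
        t = np.asarray(t, dtype=float)
        return self.lam[self.interval_of(t)]

    def node_age_density_grid(self, crown_age: float, n_grid: int = 4096):
        """Discretized density ∝ lambda(t) p1(t) of reconstructed-node ages on (0, crown_age).

        Under a birth-death-sampling process conditioned on the crown age,
        the non-crown node ages of the reconstructed tree are iid with this
        density (coalescent-point-process property).  Returns (grid, cdf)
        for inverse-transform sampling.
        """
        # place grid points strictly inside intervals; include boundaries
        t = np.linspace(0.0, crown_age, n_grid)
        _, lp1 = self.p0_logp1(t)
        w = np.log(self.lam_at(t)) + lp1
        w = np.exp(w - w.max())
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(t))])
        if cdf[-1] <= 0:
            raise ValueError("degenerate node-age density")
        return t, cdf / cdf[-1]
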