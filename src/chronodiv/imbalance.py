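"""Topology-based diversification heterogeneity.

Two classical tools:

* Maximum-likelihood estimation of Aldous' beta-splitting parameter.  Under
  the equal-rates Markov (ERM/Yule) null every lineage is equally likely to
  split and beta = 0; beta < 0 means clades split more unevenly (imbalance),
  beta > 0 more evenly.  The likelihood is a product over internal nodes of
  the split-size distribution q_n(i).
* The relative cladogenesis (RC) test: for each lineage alive at time t, the
  probability that it left at least r of the N extant tips if, under the
  constant-rates null, all k lineages alive at t were exchangeable.  A
  uniform "broken-stick" composition argument gives the closed form; tests
  across nodes are Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln, logsumexp

from .chronogram import Chronogram, SplitRecord

__all__ = [
    "BetaFit",
    "RCNode",
    "RCResult",
    "beta_split_loglik",
    "estimate_beta",
    "rc_test",
    "rc_probability",
    "BETA_LOWER",
    "BETA_UPPER",
]

BETA_LOWER = -2.0 + 1e-6
BETA_UPPER = 10.0
_PROFILE_DROP = 1.92  # chi2(1)/2 at 95%


# ---------------------------------------------------------------------
# beta splitting


def _log_split_probs(n: int, beta: float) -> np.ndarray:
    """log q of ordered splits (i, n-i), i = 1..n-1, normalized."""
    i = np.arange(1, n)
    logw = (
        gammaln(beta + i + 1)
        + gammaln(beta + n - i + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
    )
    return logw - logsumexp(logw)


def beta_split_loglik(splits, beta: float) -> float:
    """Log-likelihood of a tree's split sizes under the beta-splitting model.

    Sums log q_n(i) over internal nodes with subtree size n >= 3, where the
    unordered split {i, n-i} has probability q_n(i) = (2 - [i = n-i]) times
    the ordered weight, normalized over i.  Cherries (n = 2) have a single
    outcome and contribute nothing.  Gamma-function ratios are evaluated in
    log space, so large subtrees do not overflow.
    """
    if beta <= -2:
        raise ValueError("beta must be > -2")
    if isinstance(splits, Chronogram):
        splits = splits.split_records()
    cache: dict[int, np.ndarray] = {}
    total = 0.0
    for s in splits:
        n = s.size
        if n < 3:
            continue
        if n not in cache:
            cache[n] = _log_split_probs(n, beta)
        i = min(s.left_tips, s.right_tips)
        lp = cache[n][i - 1]
        if 2 * i != n:
            lp += np.log(2.0)
        total += lp
    return float(total)


@dataclass(frozen=True)
class BetaFit:
    """ML beta-splitting estimate with a profile-likelihood 95% CI."""

    beta_hat: float
    log_likelihood: float
    ci_low: float
    ci_high: float


def estimate_beta(tree) -> BetaFit:
    """Maximum-likelihood beta over internal-node split sizes.

    Bounded scalar maximization on (-2, 10]; the 95% CI is the profile
    likelihood interval at a log-likelihood drop of 1.92, clamped to the
    search bounds when the profile never crosses.
    """
    splits = tree.split_records() if isinstance(tree, Chronogram) else list(tree)
    n_tips = max(s.size for s in splits)
    if n_tips < 4:
        raise ValueError("beta estimation needs at least 4 tips")

    def nll(b):
        return -beta_split_loglik(splits, b)

    res = minimize_scalar(nll, bounds=(BETA_LOWER, BETA_UPPER), method="bounded",
                          options={"xatol": 1e-6})
    bhat = float(res.x)
    ll_hat = -float(res.fun)
    # endpoints can beat the interior optimum when the profile is monotone
    for b_end in (BETA_LOWER, BETA_UPPER):
        ll_end = -nll(b_end)
        if ll_end > ll_hat:
            bhat, ll_hat = b_end, ll_end

    def drop(b):
        return (-nll(b)) - (ll_hat - _PROFILE_DROP)

    lo = BETA_LOWER
    if drop(BETA_LOWER) < 0 and bhat > BETA_LOWER:
        lo = brentq(drop, BETA_LOWER, bhat, xtol=1e-6)
    hi = BETA_UPPER
    if drop(BETA_UPPER) < 0 and bhat < BETA_UPPER:
        hi = brentq(drop, bhat, BETA_UPPER, xtol=1e-6)
    return BetaFit(bhat, ll_hat, float(lo), float(hi))


# ---------------------------------------------------------------------
# relative cladogenesis test


def rc_probability(k: int, N: int, r: int) -> float:
    """P(a focal one of k exchangeable lineages leaves >= r of N tips).

    Under the ERM null the composition of N tips among k lineages is uniform
    over the C(N-1, k-1) positive compositions, giving

        P = sum_{j=r}^{N-k+1} C(N-j-1, k-2) / C(N-1, k-1).

    Computed with log-gamma ratios for numerical range.
    """
    if not (2 <= k <= N) or not (1 <= r):
        raise ValueError("need 2 <= k <= N and r >= 1")
    if r > N - k + 1:
        return 0.0
    j = np.arange(r, N - k + 2)
    lognum = gammaln(N - j) - gammaln(k - 1) - gammaln(N - j - k + 2)
    logden = gammaln(N) - gammaln(k) - gammaln(N - k + 1)
    return float(np.exp(logsumexp(lognum) - logden))


@dataclass(frozen=True)
class RCNode:
    node_id: int
    subtree_age: float    # age of the focal node (Ma)
    stem_age: float       # origin of the focal lineage = parent node age (Ma)
    r: int                # tips descending from the focal lineage
    k: int                # lineages alive immediately after the stem age
    N: int                # tips descending from those k lineages
    p_raw: float
    p_corrected: float
    flagged: bool


@dataclass(frozen=True)
class RCResult:
    nodes: list
    alpha: float
    n_tested: int

    @property
    def flagged(self) -> list:
        return [nd for nd in self.nodes if nd.flagged]


def rc_test(tree: Chronogram, alpha: float = 0.05) -> RCResult:
    """Relative cladogenesis test over every non-root internal node.

    Each internal lineage is dated at its stem (its parent node's age t);
    k counts the lineages alive immediately after t (branchings at exactly
    t included), and the lineage is asked whether its r descendant tips are
    too many among the N = total tips under the exchangeable null.  Raw
    p-values are Bonferroni-corrected by the number of tested nodes;
    results are reported root-to-tip (oldest stem first).  Tips are skipped:
    r = 1 gives p = 1 identically.
    """
    if tree.n_tips < 3:
        raise ValueError("RC test needs at least 3 tips")
    counts = tree._subtree_tip_counts()
    bt_ages = tree.branching_times().ages
    N = tree.n_tips
    recs = []
    for i in range(len(tree.parent)):
        if tree.children[i] is None or tree.parent[i] < 0:
            continue
        t = float(tree.age[tree.parent[i]])
        k = 1 + int(np.sum(bt_ages >= t - 1e-12))
        r = int(counts[i])
        recs.append((i, float(tree.age[i]), t, r, k))
    m = len(recs)
    nodes = []
    for (i, age_i, t, r, k) in sorted(recs, key=lambda x: -x[2]):
        p = rc_probability(k, N, r)
        pc = min(1.0, p * m)
        nodes.append(RCNode(i, age_i, t, r, k, N, p, pc, pc < alpha))
    return RCResult(nodes, alpha, m)
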