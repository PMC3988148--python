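"""Branching-time statistics: gamma/MCCR, lineage-through-time series,
null envelopes, per-epoch linear fits, and sliding-window diversification rates.

Time is measured backward in Ma (age 0 = present).  The gamma statistic of
Pybus & Harvey standardizes the position of nodes relative to the constant
pure-birth expectation: gamma < 0 means nodes sit closer to the root
(a diversification slowdown), gamma > 0 closer to the tips.  The MCCR
(Monte-Carlo constant-rates) test recalibrates gamma's null by simulating
complete pure-birth trees and pruning them to the sampled taxon count,
removing the bias incomplete sampling induces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chronogram import BranchingTimes, Chronogram
from .simulate import _rng, simulate_yule, yule_branching_times

__all__ = [
    "GammaResult",
    "LTTSeries",
    "WindowRecord",
    "SegmentFit",
    "gamma_stat",
    "mccr_test",
    "ltt_series",
    "ltt_envelope",
    "ltt_segment_fit",
    "sliding_window_rates",
    "lineage_count_at",
    "TABLE_PERIODS",
]

#: default epochs (start, end ages in Ma) for per-period LTT linear fits:
#: Eocene–early Oligocene, early Oligocene–early Miocene, early–mid Miocene,
#: mid–late Miocene, late Miocene, Pliocene–present.
TABLE_PERIODS = [(50, 30), (30, 20), (20, 15), (15, 10), (10, 5), (5, 0)]


def _as_bt(x) -> BranchingTimes:
    return x.branching_times() if isinstance(x, Chronogram) else x


# ---------------------------------------------------------------------
# gamma


def gamma_stat(bt) -> float:
    """Pybus-Harvey gamma statistic of a set of branching times.

    With g_k the duration during which the reconstructed tree has k lineages
    (k = 2..n) and T_j = sum_{k<=j} k g_k, T = T_n:

        gamma = [ mean_{j=2..n-1} T_j  -  T/2 ] / [ T sqrt(1 / (12 (n-2))) ]

    Asymptotically standard normal under constant-rate pure birth.
    """
    bt = _as_bt(bt)
    n = bt.n_tips
    if n < 4:
        raise ValueError("gamma requires at least 4 tips")
    xs = np.append(bt.ages, 0.0)
    g = -np.diff(xs)  # g_2 .. g_n
    k = np.arange(2, n + 1)
    T = np.cumsum(k * g)
    total = T[-1]
    num = T[:-1].mean() - total / 2.0
    den = total * np.sqrt(1.0 / (12.0 * (n - 2)))
    return float(num / den)


# ---------------------------------------------------------------------
# MCCR / constant-rate test


@dataclass(frozen=True)
class GammaResult:
    """Observed gamma against a simulated pure-birth null."""

    gamma: float
    p_value: float
    null_quantiles: dict
    n_reps: int
    n_total: int
    n_sampled: int
    two_sided: bool = False


def _pruned_branching_ages(tree: Chronogram, keep_tips: np.ndarray) -> np.ndarray:
    """Node ages of the subtree induced by a subset of tips (descending).

    A node survives pruning iff both its child subtrees retain at least one
    kept tip; its age is unchanged (uniform-sampling semantics).
    """
    n = len(tree.parent)
    cnt = np.zeros(n, dtype=int)
    cnt[keep_tips] = 1
    ages = []
    for i in range(n - 1, -1, -1):
        ch = tree.children[i]
        if ch is not None:
            a, b = cnt[ch[0]], cnt[ch[1]]
            cnt[i] = a + b
            if a >= 1 and b >= 1:
                ages.append(tree.age[i])
    return np.sort(np.asarray(ages))[::-1]


def mccr_test(
    gamma_obs: float,
    n_sampled: int,
    n_total: int,
    reps: int = 1000,
    prune: bool = True,
    seed=None,
    two_sided: bool = False,
) -> GammaResult:
    """Monte-Carlo constant-rates test for gamma under incomplete sampling.

    Simulates ``reps`` pure-birth trees with ``n_total`` tips; if ``prune``
    each is uniformly pruned to ``n_sampled`` tips before computing gamma.
    The one-sided (lower-tail, slowdown-direction) p-value uses the
    add-one estimator p = (1 + #{gamma_sim <= gamma_obs}) / (reps + 1).
    With ``prune=False`` and ``n_total == n_sampled`` this is the plain
    constant-rate test.
    """
    if n_sampled > n_total:
        raise ValueError("n_sampled cannot exceed n_total")
    if n_sampled < 4:
        raise ValueError("need at least 4 sampled tips")
    if reps < 100:
        raise ValueError("use at least 100 simulation replicates")
    rng = _rng(seed)
    null = np.empty(reps)
    do_prune = prune and n_sampled < n_total
    for r in range(reps):
        if do_prune:
            tree = simulate_yule(n_total, 1.0, rng)
            keep = rng.choice(tree.tip_indices, size=n_sampled, replace=False)
            ages = _pruned_branching_ages(tree, keep)
            null[r] = gamma_stat(BranchingTimes(ages, n_sampled))
        else:
            null[r] = gamma_stat(yule_branching_times(n_total, 1.0, rng))
    lower = (1 + np.sum(null <= gamma_obs)) / (reps + 1)
    if two_sided:
        upper = (1 + np.sum(null >= gamma_obs)) / (reps + 1)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        p = lower
    qs = {f"{q:g}": float(np.percentile(null, q)) for q in (2.5, 5, 50, 95, 97.5)}
    return GammaResult(float(gamma_obs), float(p), qs, reps, n_total, n_sampled, two_sided)


# ---------------------------------------------------------------------
# LTT


@dataclass(frozen=True)
class LTTSeries:
    """Lineage count as a function of node age (descending ages)."""

    ages: np.ndarray
    counts: np.ndarray
    n_tips: int


def ltt_series(bt) -> LTTSeries:
    """(age, lineage count) pairs: the count jumps at each branching age."""
    bt = _as_bt(bt)
    counts = np.arange(2, bt.n_tips + 1)
    return LTTSeries(bt.ages.copy(), counts, bt.n_tips)


def lineage_count_at(bt, t) -> np.ndarray:
    """Reconstructed lineage count at backward age(s) t.

    Right-continuous in backward time: a branching exactly at t counts as
    already-born, so the count at the crown age is 2.
    """
    bt = _as_bt(bt)
    t = np.asarray(t, dtype=float)
    # ages descending; count = 1 + #{ages >= t}, clipped to 1 above the crown
    cnt = 1 + np.searchsorted(-bt.ages, -t, side="right")
    return np.where(t > bt.ages[0], 1, cnt)


@dataclass(frozen=True)
class LTTEnvelope:
    grid: np.ndarray              # ages, descending from crown to 0
    log_obs: np.ndarray           # ln lineage count of the observed tree
    band50: np.ndarray            # (2, len(grid)) central 50% of ln counts
    band95: np.ndarray            # (2, len(grid)) central 95%
    excluded: np.ndarray          # observed outside the 95% band
    n_reps: int


def ltt_envelope(tree: Chronogram, reps: int = 1000, seed=None, n_grid: int = 201) -> LTTEnvelope:
    """Pointwise null bands for the log-LTT under matched pure-birth trees.

    Null trees are simulated with the observed tip count and rescaled to the
    observed crown age (the joint root-height/taxon-count conditioning of the
    null is approximated by rescaling).  Bands are the central 50% and 95%
    of ln(lineage count) on a common age grid.
    """
    bt = tree.branching_times()
    rng = _rng(seed)
    grid = np.linspace(bt.crown_age, 0.0, n_grid)
    sims = np.empty((reps, n_grid))
    for r in range(reps):
        sim = yule_branching_times(tree.n_tips, 1.0, rng).rescaled(bt.crown_age)
        sims[r] = np.log(lineage_count_at(sim, grid))
    band50 = np.percentile(sims, [25, 75], axis=0)
    band95 = np.percentile(sims, [2.5, 97.5], axis=0)
    log_obs = np.log(lineage_count_at(bt, grid))
    excluded = (log_obs < band95[0]) | (log_obs > band95[1])
    return LTTEnvelope(grid, log_obs, band50, band95, excluded, reps)


# ---------------------------------------------------------------------
# per-epoch linear fits


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of the (log-)LTT within one geological period."""

    period: tuple
    slope: float
    intercept: float
    n_points: int
    scale: str
    ok: bool

    @property
    def start(self) -> float:
        return self.period[0]

    @property
    def end(self) -> float:
        return self.period[1]


def ltt_segment_fit(series: LTTSeries, periods=None, scale: str = "log") -> list[SegmentFit]:
    """Fit lineage count (log by default) against time within each period.

    ``periods`` are (start, end) ages in Ma with start > end; the regressor
    is forward time −age so slopes read "per Ma toward the present".  A
    period holding fewer than two branching events yields a flagged,
    undefined fit rather than being dropped.
    """
    if periods is None:
        periods = TABLE_PERIODS
    if scale not in ("log", "raw"):
        raise ValueError("scale must be 'log' or 'raw'")
    out = []
    for (start, end) in periods:
        if start <= end:
            raise ValueError("each period needs start > end (ages in Ma)")
        sel = (series.ages <= start) & (series.ages >= end)
        x = -series.ages[sel]
        y = series.counts[sel].astype(float)
        if scale == "log":
            y = np.log(y)
        if len(x) < 2 or np.ptp(x) == 0:
            out.append(SegmentFit((start, end), np.nan, np.nan, int(len(x)), scale, False))
            continue
        res = stats.linregress(x, y)
        out.append(
            SegmentFit((start, end), float(res.slope), float(res.intercept), int(len(x)), scale, True)
        )
    return out


# ---------------------------------------------------------------------
# sliding windows


@dataclass(frozen=True)
class WindowRecord:
    start: float    # older edge (Ma)
    end: float      # younger edge (Ma)
    nb: int         # lineages at the older edge
    nt: int         # lineages at the younger edge
    rate: float     # -ln(Nb/Nt)/width, per lineage per Ma
    valid: bool


def sliding_window_rates(
    bt, width: float = 5.0, step: float = 1.0, t_old: float = 56.0, t_young: float = 2.6
) -> list[WindowRecord]:
    """Sliding-window net diversification rate −ln(Nb/Nt)/Δt.

    Windows [a, a−width] step by ``step`` from ``t_old`` toward the present,
    stopping once the younger edge would pass ``t_young``.  Nb and Nt are
    the lineage counts at the older and younger edges; windows whose older
    edge predates the crown are reported but flagged invalid.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if t_old <= t_young:
        raise ValueError("t_old must exceed t_young")
    bt = _as_bt(bt)
    out = []
    a = float(t_old)
    while a - width >= t_young - 1e-9:
        b = a - width
        if a > bt.crown_age:
            out.append(WindowRecord(a, b, 0, 0, np.nan, False))
        else:
            nb = int(lineage_count_at(bt, a))
            nt = int(lineage_count_at(bt, b))
            out.append(WindowRecord(a, b, nb, nt, float(-np.log(nb / nt) / width), True))
        a -= step
    return out
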