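# Methods

This note records the models implemented in `chronodiv`, the conventions
that make their likelihoods mutually comparable, and the numerical and
design choices a maintainer would want to know. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Time and tree conventions

All ages are measured backward from the present in Ma: tips sit at age 0,
the crown (most recent common ancestor of the sampled tips) is the oldest
node. A chronogram must be rooted, strictly binary and ultrametric;
root-to-tip path lengths may disagree by up to a relative 1e−6 of the crown
age (dating software emits rounding noise at this level), after which tip
ages are snapped to exactly 0. Tied node ages are legal and kept as
distinct events, ordered by a stable sort. The n−1 internal-node ages in
descending order (`BranchingTimes`) are the sufficient statistic for every
temporal method; per-node split sizes (`SplitRecord`) are the sufficient
statistic for the topological ones.

Lineage counts through time are right-continuous in backward time: a
branching exactly at age t counts as already-born at t, so the count at the
crown age is 2. This convention also fixes which lineages are "alive" at a
window edge in the sliding-window rate and at a stem age in the RC test.

## γ and the MCCR test

γ follows Pybus & Harvey (2000): with g_k the duration during which the
reconstructed tree has k lineages and T_j = Σ_{k≤j} k·g_k,

γ = [ mean_{j=2..n−1} T_j − T_n/2 ] / [ T_n √(1/(12(n−2))) ],

asymptotically standard normal under constant-rate pure birth and exactly
scale-invariant. The MCCR test simulates complete pure-birth trees of
`n_total` tips, uniformly prunes each to the `n_sampled` observed tips, and
compares the observed γ with the pruned null. The p-value uses the add-one
estimator (1 + #{γ_sim ≤ γ_obs})/(reps + 1), which cannot return 0; the
default is one-sided in the slowdown (lower-tail) direction because that is
the direction a negative γ is interpreted in; a two-sided option exists.
With `prune=False` and `n_total = n_sampled` the function is the plain
constant-rate test. Pruned simulated trees keep their original node ages
(uniform-sampling semantics), so the null correctly absorbs the
"apparent slowdown" bias that incomplete sampling induces.

## LTT envelopes, segment fits, sliding windows

Null LTT envelopes simulate pure-birth trees conditioned on the observed
tip count and linearly rescale each to the observed crown age, then take
pointwise central 50% and 95% intervals of ln(count) on a common age grid
(default 201 points). Rescaling is an approximation to exact joint
(root height, tip count) conditioning; it is the simplest reproducible
reading and is what the envelope's coverage test exercises.

Per-epoch fits regress lineage count against forward time (−age) by
ordinary least squares within user-supplied periods; the default period set
is the six Cenozoic epochs (50–30, 30–20, 20–15, 15–10, 10–5, 5–0 Ma). The
default scale is logarithmic — under constant birth–death the expected
log-LTT is linear with slope λ − μ — and a raw scale is available because
published per-epoch slope tables are not always attributable to either
scale. A period containing fewer than two events yields a flagged undefined
fit rather than being dropped.

Sliding windows of width 5 Ma step 1 Ma (defaults; the canonical span runs
from 56 Ma to the Pleistocene boundary at 2.6 Ma) report
rate = −ln(N_b/N_t)/Δt with N_b, N_t the counts at the older and younger
edges. Windows whose older edge predates the crown are reported and flagged
invalid instead of silently skipped.

## Imbalance: β-splitting and the RC test

The β-splitting likelihood treats each internal node of subtree size n ≥ 3
as an independent draw of an unordered split {i, n−i} with probability
proportional to (2 − [i = n−i]) · Γ(β+i+1)Γ(β+n−i+1)/(Γ(i+1)Γ(n−i+1)),
normalized over ordered splits i = 1..n−1. Cherries are uninformative. All
Γ ratios are evaluated as log-gamma differences, so subtree sizes in the
hundreds do not overflow. The MLE is found by bounded scalar search on
(−2 + 1e−6, 10]; above 10 the split kernel is numerically indistinguishable
from perfect balance at these tree sizes, and the bounds are themselves
checked so a monotone profile reports the boundary rather than a spurious
interior optimum. The 95% CI is the profile-likelihood interval at a
log-likelihood drop of 1.92 (χ²₁/2), clamped to the search bounds — a
deterministic and testable choice.

The RC test evaluates every non-root internal lineage, dated at its stem
(its parent node's age t). With k lineages alive immediately after t and
N total sampled tips, the probability that an exchangeable focal lineage
leaves at least r tips is the uniform-composition tail

P = Σ_{j=r}^{N−k+1} C(N−j−1, k−2) / C(N−1, k−1),

computed with log-gamma ratios and verified in the tests against exhaustive
enumeration of all compositions for k ≤ 5, N ≤ 12. Tips are excluded
(r = 1 gives P = 1 identically); the Bonferroni factor is the number of
tested nodes, and results are reported stem-age-descending (root to tip).

## Likelihood conventions for model competition

All pure-birth-family models (Yule, Yule-2/3-rate, DDL, DDX) share one
convention: with N(t) lineages the next event arrives at rate N(t)·λ(t),
and the exposure sum includes the terminal interval from the last branching
to the present,

ℓ = Σ_events ln λ(t_event) − Σ_k N_k λ_k g_k,

summed over the n−2 post-crown branching events (the crown split is
conditioned on, not modeled). The Yule MLE is then the closed form
λ̂ = (n−2)/Σ k·g_k, identical to the classical crown-conditioned estimator.
The constant birth–death model uses the reconstructed-process likelihood
conditioned on crown survival (the 0-shift case of the piecewise kernel
below); as μ → 0 it reduces **exactly** to the Yule form, which keeps AIC
comparisons across the rate-constant/rate-variable divide internally
coherent. Parameter counts: Yule 1, birth–death 2, Yule-2-rate 3,
Yule-3-rate 5, DDL 2, DDX 2; AIC = 2k − 2ℓ (AIC, not AICc).

Breakpoints of the Yule-2/3-rate models are profiled exhaustively over the
observed branching times plus the midpoints of inter-event intervals
(including the interval ending at the present); within regimes the rate MLE
is closed-form e_j/E_j, with an empty regime contributing 0 (the λ → 0
limit). The second breakpoint is added best-first: the Yule-2 optimum is
held fixed while the other candidate is profiled. An event exactly at a
breakpoint belongs to the older regime (it occurred at the old rate). DDX
profiles λ₀ in closed form and searches x ∈ [0, 10]; DDL profiles λ₀ and
searches u = 1/K ∈ [0, 1/(n+ε)), where u = 0 is the Yule limit. Both
boundary optima (x = 0, K = ∞) are evaluated explicitly and reported as
flags, never hidden, so the nesting inequalities
ℓ(bd) ≥ ℓ(yule), ℓ(yule3) ≥ ℓ(yule2) ≥ ℓ(yule), ℓ(ddx) ≥ ℓ(yule),
ℓ(ddl) ≥ ℓ(yule) hold on every input by construction.

ΔAIC_RC = min AIC(Yule, bd) − min AIC(Yule2, Yule3, DDL, DDX); positive
values favor temporal rate variation. ΔAIC_RC is invariant to time
rescaling (a tested property), so null critical values are simulated at
λ = 1 without loss of generality.

### A note on published ΔAIC_RC critical values

The critical values commonly cited for this statistic — about 4 at 30 taxa
and 5.5 at 100 taxa, originating with Rabosky's `laser` toolkit — depend on
that implementation's internal conditioning and breakpoint-search
restrictions, which were never published in equation form. Under the
convention fixed here (terminal-exposure included, breakpoints free over
event times and midpoints) the simulated 95% null quantiles are
reproducibly larger: ≈ 6.2 at n = 30 and ≈ 7.6 at n = 100 (the acceptance
script recomputes both). The magnitude is what change-point theory predicts
for a sup-LRT with two free parameters per regime (2Δℓ ≈ 10 at the 95th
percentile). Restricting candidates to event times only, to interior event
times, or truncating null trees at the n-th speciation moves the quantile
by at most ≈ 0.5 — none of these reproduces 4. Users comparing against the
literature constants should therefore calibrate with
`daic_critical_value` at their own tree size rather than reusing published
numbers across implementations; the package's tests document (and do not
paper over) this discrepancy.

## Piecewise birth–death-sampling likelihood and shift search

The shift model is a birth–death process with piecewise-constant (λ_i, μ_i)
on intervals delimited by shift times (present-most interval first) and
present-day sampling probability ρ. Two kernel functions of a lineage alive
at age t drive everything: p0(t), the probability of leaving no sampled
descendant, and p1(t), the probability of exactly one sampled descendant
lineage. Both satisfy Riccati/linear ODEs with closed-form per-interval
solutions; across boundaries they propagate by continuity, and p1 is
carried in log space throughout (for old lineages it underflows long before
the likelihood does). The λ = μ case uses the critical-process limit, and
initial conditions at the μ/λ equilibrium are special-cased. The kernels
are validated in the tests against brute-force stochastic simulation of
their definitions across a rate shift, and against the textbook
constant-rate expressions.

Conditioned on the crown age and on both crown lineages surviving to
sampling, the log-likelihood of the node ages x₁ ≥ x₂ ≥ … is

ℓ = Σ_{i≥2} [ln λ(x_i) + ln p1(x_i)] + 2 ln p1(x₁) − 2 ln(1 − p0(x₁)).

With no shifts, ρ = 1 and μ = 0 this reduces exactly to the Yule form
above. Intervals are parameterized by turnover ε = μ/λ and net
diversification r = λ − μ (the quantities shift tables print); the
optimizer works on (log λ, logit(ε/2)), so ε ranges over (0, 2): values in
(1, 2) encode decline regimes (r < 0) and are flagged `decline-regime` in
the output. Note that the exact likelihood is genuinely discontinuous in a
shift time at the measure-zero instant it crosses a branching age (the
event's λ factor switches); continuity holds, and is tested, in the rate
parameters and in the shift time between events.

The stepwise search mirrors the grid protocol of shift-detection practice:
candidates on a fixed grid (default 34–3 Ma, 1 Ma spacing, restricted to
inside the tree span); at each round the best single new shift is added
with previous shifts held fixed, and an LRT compares m shifts against m−1
using a χ² reference with 3 degrees of freedom per added shift (shift time
plus one (ε, r) pair) — the reference is stated in the output because it is
a convention, not a theorem, for grid-constrained shift times. Per-round
optimization uses a scan-then-polish budget: every candidate is fitted from
a warm start (the parent model's rates, with the split interval
duplicated) plus one cold start, and the three best candidates are refitted
with the full five-start budget (Nelder–Mead, seeded starts). Shift times
stay on the grid; no continuous refinement follows. ρ is a fixed input, not
estimated; the 0-shift row re-expresses the constant birth–death fit in
(Tu, Div) form.

## Simulators

`simulate_yule` draws the k-lineage durations g_k ~ Exp(k·λ) directly and
assembles a uniform ranked topology by random pair joins — exactly the
forward pure-birth process started from 2 crown lineages, stopped at the
n-th tip with a final hang interval distributed as the wait to the next
event. This stopping rule makes all g_k independent exponentials, which is
the null the γ statistic, the MCCR test, the LTT envelope and the ΔAIC_RC
calibration all assume.

`simulate_bd_reconstructed` is an event-driven forward birth–death
simulation. Without shift times it runs until `n_tips` lineages are extant
(plus the hang interval) — a first-passage stopping rule that is exact for
pure birth and a standard, slightly approximate convention when extinction
is present. With shift times (which are calendar ages) a total duration
must be supplied; the run is conditioned on at least `n_tips`/ρ survivors
with a retry budget of 1000, extinct lineages are pruned, and a uniform
subset of tips is retained (ρ-subsampling keeps round(ρ·n) tips in
taxon-stop mode). Exhausting the retry budget raises an error — a signal
that the requested conditioning contradicts the rates — never a silent
fallback.

`simulate_bd_conditioned` draws the reconstructed tree exactly from its
conditional law: given the crown age, the remaining n−2 node ages are iid
with density ∝ λ(t)·p1(t) (the coalescent-point-process property), sampled
by inverse transform on a 4096-point grid, and the ranked topology is
uniform. This is how the bundled slowdown scenario is generated: at net
rate 0.058 a crown 55.7 Ma old is expected to leave only ≈ 13 extant
lineages, so forward rejection conditioned on ≈ 100 survivors is hopeless,
while the conditional draw is exact and O(n). The coupling between this
sampler and the likelihood (both use the p0/p1 kernels) is broken by the
kernels' independent brute-force validation and by the forward simulator's
distributional cross-checks at constant rates.

`simulate_beta_splitting_topology` recursively splits clades with the
β-kernel; its branch lengths are placeholders ((size−1)/(n−1) node ages)
because only split sizes carry signal.

`make_nerita_like` fixes the study conditions of the bundled scenario:
74 sampled tips of ~100 extant lineages (ρ = 0.74), crown age 55.7 Ma, one
shift at 24 Ma with net diversification 0.058 → 0.00013 and turnover
0.57 → 0.99 (present-first ordering: the low-rate regime is the recent
one). `shift=False` applies the pre-shift rates throughout, as a matched
constant-rate control.

### What the generators do and do not emulate

Simulated chronograms are exact draws from the stated processes: no dating
error, no topological uncertainty, no among-lineage rate heterogeneity
beyond the modeled shifts, and uniform (not clade-biased) taxon sampling.
Passing tests therefore demonstrate the estimators' correctness and power
under their own model assumptions; they do not certify behavior on real
chronograms, where node-age error and non-uniform sampling are the dominant
extra noise sources.

## Reproducibility and problem sizes

Every stochastic routine takes a seed; the pipeline derives one sub-seed
per stage by hashing the stage name with the root seed (all below 2³¹), so
identical (config, seed) pairs produce byte-identical JSON reports and any
stage can be re-run in isolation. Problem sizes in the test suite and
acceptance script are the package's calibration choices: 1000 pure-birth
trees of 100 tips for the γ critical value; 1000 and 250 replicates for the
ΔAIC_RC null at 30 and 100 tips; 500 equal-rates topologies of 74 tips for
the β centering check; 20 scenario replicates for shift-time recovery and
100 for breakpoint recovery; 200 pure-birth runs (95%-nominal checks need
that many to resolve a 90% pass criterion) for the joint null-behavior
suite.

## Known limitations

- The forward birth–death simulator's first-passage conditioning is not the
  exact n-tip conditioned law when μ > 0; use `simulate_bd_conditioned`
  when exactness matters.
- The β CI is profile-likelihood only; no bootstrap alternative.
- The shift search treats ρ as known; misspecifying it biases turnover more
  than it biases shift placement.
- Published ΔAIC_RC critical values are implementation-specific (see above);
  only same-convention, simulation-calibrated values should be used.
- Mass-extinction (sampled-past) events, time-varying ρ, trait-dependent
  diversification and Nexus/PhyloXML I/O are out of scope.
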