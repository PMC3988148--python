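"""Rate-constant vs rate-variable model competition with dAIC_RC.

Fits Yule and birth-death (rate-constant) against Yule-2/3-rate and the
density-dependent DDL/DDX models, and calibrates the dAIC_RC statistic by
simulating its pure-birth null at the observed tree size.
"""

from chronodiv import daic_critical_value, delta_aic_rc, make_nerita_like

tree = make_nerita_like(seed=13)
res = delta_aic_rc(tree.branching_times(), seed=0)

print(f"{'model':<7}{'class':<6}{'logL':>10}{'k':>3}{'AIC':>10}")
for m in res.all_fits:
    cls = "RC" if m.name in ("yule", "bd") else "RV"
    print(f"{m.name:<7}{cls:<6}{m.log_likelihood:>10.3f}{m.n_params:>3}{m.aic:>10.3f}")

crit, _ = daic_critical_value(tree.n_tips, reps=200, seed=1)
print(f"\ndAIC_RC = {res.daic:.2f}  (simulated 95% critical value {crit:.2f})")
print("rate-constant models", "rejected" if res.daic > crit else "not rejected")
# large positive dAIC means the rate-variable family fits far better than
# any constant-rate model can — expected for the built-in slowdown scenario
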