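"""Simulate chronograms under the processes the analyses calibrate against.

Builds a pure-birth tree, a birth-death tree with incomplete sampling, and
the built-in Nerita-like slowdown scenario, and prints their basic shape.
"""

from chronodiv import SimParams, make_nerita_like, simulate_bd_reconstructed, simulate_yule

yule = simulate_yule(n_tips=50, lam=0.5, seed=1)
print(f"pure birth      : {yule.n_tips} tips, crown {yule.crown_age:.2f} Ma")

bd = simulate_bd_reconstructed(
    SimParams(n_tips=100, lam=(1.0,), mu=(0.5,), rho=0.6, seed=2)
)
print(f"birth-death ρ=.6: {bd.n_tips} tips, crown {bd.crown_age:.2f} Ma")

nerita = make_nerita_like(seed=3)
print(f"slowdown scenario: {nerita.n_tips} tips, crown {nerita.crown_age:.2f} Ma")
print("newick prefix   :", nerita.to_newick()[:70], "...")

# crown ages scale inversely with the speciation rate; the scenario tree is
# pinned at 55.7 Ma with a rate shift at 24 Ma and 74 of ~100 lineages sampled
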