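"""Fit the model variants to a simulated dataset and compare by AIC.

Simulates one island under clade-specific diversity-dependence, fits the
diversity-independent (DI) and CS (no anagenesis) variants, and prints the
information-criterion table.
"""

from islandbd import (
    ModelParams,
    ModelSpec,
    fit_model,
    information_criteria,
    simulate_cs,
)

p_true = ModelParams(lambda_c0=0.44, mu=0.11, K=36.45, gamma0=0.0002, lambda_a=0.0)
ds = simulate_cs(p_true, island_age=30.0, M=1000, seed=15).dataset
print(f"simulated dataset: {ds.n_clades} clades, {ds.total_species} species")

fits = []
for spec in (ModelSpec("DI", True), ModelSpec("CS", True)):
    fr = fit_model(ds, spec, n_starts=1, seed=4, max_evals=300, fatol=1e-3)
    fits.append(fr)
    print(f"{spec.label:10s} loglik {fr.loglik:9.3f}  MLEs {fr.params.as_dict()}")

print()
print(information_criteria(fits).to_string(index=False))
print(
    "\nThe diversity-dependent model should carry most of the AIC weight when\n"
    "the generating process had a finite clade-level carrying capacity."
)
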