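"""Reusable simulation experiments: estimator precision and model misselection.

These wrap the simulator, the fitting machinery and the bootstrap into the two
study designs used to validate the method: (i) parametric-bootstrap precision
of the CS estimates (fit the generating model to its own simulations and look
at the medians), and (ii) the rate at which plain highest-likelihood selection
picks the wrong model between CS and IW.  Replication counts are arguments;
the full-scale versions of these experiments are compute-heavy, so callers
choose the scale.
"""

from __future__ import annotations

import numpy as np

from .data import validate_dataset
from .fit import FitResult, fit_model
from .rates import ModelParams, ModelSpec
from .select import BootstrapResult, bootstrap_lrt
from .simulate import simulate_cs, simulate_iw

__all__ = ["recovery_experiment", "misselection_experiment"]


def recovery_experiment(
    p_true: ModelParams,
    n_reps: int,
    seed: int,
    *,
    island_age: float = 30.0,
    M: int = 1000,
    variant: str = "CS",
    anagenesis_fixed_zero: bool = True,
    max_evals: int = 500,
    fatol: float = 1e-4,
) -> dict:
    """Simulate under ``p_true``, refit the generating model, report medians.

    Degenerate replicates (empty islands, recolonization doublets) carry no
    usable signal for the fit and are skipped, with extra simulations drawn to
    keep ``n_reps`` fitted datasets.  Starts at the generating parameters, the
    parametric-bootstrap protocol.
    """
    spec = ModelSpec(variant, anagenesis_fixed_zero)
    sim = simulate_cs if variant == "CS" else simulate_iw
    rng = np.random.default_rng(seed)
    estimates = []
    n_skipped = 0
    tries = 0
    while len(estimates) < n_reps and tries < 10 * n_reps:
        tries += 1
        ds = sim(p_true, island_age, M, rng=rng).dataset
        if ds.n_clades == 0 or validate_dataset(ds):
            n_skipped += 1
            continue
        floor = (
            max(c.n_species for c in ds.clades) if variant == "CS" else ds.total_species
        )
        fr = fit_model(
            ds,
            spec,
            n_starts=1,
            seed=int(rng.integers(0, 2**31 - 1)),
            start_params=p_true.with_(K=max(p_true.K, floor + 1.0)),
            max_evals=max_evals,
            fatol=fatol,
        )
        estimates.append(
            [fr.params.lambda_c0, fr.params.mu, fr.params.K, fr.params.gamma0]
        )
    est = np.array(estimates)
    truth = np.array([p_true.lambda_c0, p_true.mu, p_true.K, p_true.gamma0])
    med = np.median(est, axis=0)
    return {
        "names": ["lambda_c0", "mu", "K", "gamma0"],
        "truth": truth,
        "medians": med,
        "rel_errors": (med - truth) / truth,
        "estimates": est,
        "n_reps": len(estimates),
        "n_skipped": n_skipped,
    }


def misselection_experiment(
    p_cs: ModelParams,
    p_iw: ModelParams,
    n_reps: int,
    seed: int,
    *,
    island_age: float = 30.0,
    M: int = 1000,
    max_evals: int = 200,
    fatol: float = 1e-3,
) -> dict:
    """Highest-likelihood misselection rates between CS and IW (both noA).

    Simulates ``n_reps`` datasets under each model's parameters, fits both
    models to every dataset, and reports the fraction where the wrong model
    has the higher loglikelihood: delta = LL_CS - LL_IW < 0 under CS
    (IW wrongly preferred), delta > 0 under IW (CS wrongly preferred).
    """
    from .data import IslandDataset

    shell = IslandDataset(island_age, M, ())  # carries the simulation conditions
    fit_cs = FitResult(ModelSpec("CS", True), p_cs, 0.0, 4, 0)
    fit_iw = FitResult(ModelSpec("IW", True), p_iw, 0.0, 4, 0)
    boot: BootstrapResult = bootstrap_lrt(
        shell,
        fit_cs,
        fit_iw,
        n_reps=n_reps,
        seed=seed,
        max_evals=max_evals,
        fatol=fatol,
    )
    d_cs, d_iw = boot.deltas_under_cs, boot.deltas_under_iw
    return {
        "deltas_under_cs": d_cs,
        "deltas_under_iw": d_iw,
        "rate_iw_preferred_under_cs": float(np.mean(d_cs < 0)) if d_cs.size else np.nan,
        "rate_cs_preferred_under_iw": float(np.mean(d_iw > 0)) if d_iw.size else np.nan,
        "n_cs": int(d_cs.size),
        "n_iw": int(d_iw.size),
        "n_failures": boot.n_failures_cs + boot.n_failures_iw,
        "n_incomplete": boot.n_incomplete,
        "pct5_cs": boot.pct5_cs,
        "pct95_iw": boot.pct95_iw,
    }
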