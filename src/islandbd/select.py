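"""Parametric-bootstrap model selection between CS and IW, and goodness-of-fit.

AIC-style selection is known to be unreliable for diversity-dependent models,
so the CS-vs-IW comparison simulates datasets under each fitted model, refits
both models to every simulated dataset, and locates the empirical
loglikelihood difference (LL_CS - LL_IW) within the two simulated difference
distributions: if it exceeds the 95th percentile of the IW-generated
distribution (and is not below the 5th percentile of the CS-generated one) the
CS model is selected; the mirrored rule selects IW; anything between is
indecisive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IslandDataset, validate_dataset
from .fit import FitResult, fit_model
from .likelihood import DEFAULT_OPTS, LikelihoodOptions
from .simulate import simulate_cs, simulate_iw

__all__ = [
    "BootstrapResult",
    "bootstrap_lrt",
    "decide_model",
    "gof_statistics",
    "GofResult",
    "gof_compare",
]


@dataclass
class BootstrapResult:
    deltas_under_cs: np.ndarray
    deltas_under_iw: np.ndarray
    pct5_cs: float
    pct95_iw: float
    empirical_delta: float
    decision: str
    n_failures_cs: int = 0
    n_failures_iw: int = 0
    n_incomplete: int = 0
    quantile_method: str = "linear"

    def as_dict(self) -> dict:
        return {
            "deltas_under_cs": list(map(float, self.deltas_under_cs)),
            "deltas_under_iw": list(map(float, self.deltas_under_iw)),
            "pct5_cs": self.pct5_cs,
            "pct95_iw": self.pct95_iw,
            "empirical_delta": self.empirical_delta,
            "decision": self.decision,
            "n_failures_cs": self.n_failures_cs,
            "n_failures_iw": self.n_failures_iw,
            "n_incomplete": self.n_incomplete,
            "quantile_method": self.quantile_method,
        }


def decide_model(
    empirical_delta: float,
    deltas_under_cs,
    deltas_under_iw,
    quantile_method: str = "linear",
) -> str:
    """Percentile decision rule on the loglikelihood difference LL_CS - LL_IW."""
    cs = np.asarray(deltas_under_cs, dtype=float)
    iw = np.asarray(deltas_under_iw, dtype=float)
    if cs.size == 0 or iw.size == 0:
        raise ValueError("empty bootstrap distributions")
    pct5_cs = float(np.percentile(cs, 5.0, method=quantile_method))
    pct95_iw = float(np.percentile(iw, 95.0, method=quantile_method))
    if empirical_delta > pct95_iw and empirical_delta >= pct5_cs:
        return "CS"
    if empirical_delta < pct5_cs and empirical_delta <= pct95_iw:
        return "IW"
    return "indecisive"


def bootstrap_lrt(
    ds: IslandDataset,
    fit_cs: FitResult,
    fit_iw: FitResult,
    n_reps: int,
    seed: int | None = None,
    opts: LikelihoodOptions = DEFAULT_OPTS,
    *,
    n_starts: int = 1,
    max_evals: int = 300,
    fatol: float = 1e-3,
    search_tail_tol: float = 1e-4,
    quantile_method: str = "linear",
) -> BootstrapResult:
    """Parametric bootstrap likelihood-ratio test between fitted CS and IW models.

    Simulates ``n_reps`` datasets under each model's MLEs and refits both
    models to every simulated dataset, starting from the empirical MLEs with
    the starting K raised to at least the simulated dataset's own floor
    (largest clade for CS, total species for IW).  Individual replicate
    failures (empty islands, recolonization doublets, optimizer failures) are
    recorded, not fatal.
    """
    rng = np.random.default_rng(seed)
    deltas = {"CS": [], "IW": []}
    failures = {"CS": 0, "IW": 0}
    incomplete = 0
    scenarios = (
        ("CS", fit_cs.params, simulate_cs),
        ("IW", fit_iw.params, simulate_iw),
    )
    for label, gen_params, sim in scenarios:
        for _ in range(n_reps):
            sim_ds = sim(gen_params, ds.island_age, ds.mainland_pool_M, rng=rng).dataset
            try:
                if sim_ds.n_clades == 0 or validate_dataset(sim_ds):
                    raise ValueError("degenerate simulated dataset")
                fits = {}
                for f in (fit_cs, fit_iw):
                    scope = f.spec.variant
                    floor = (
                        max(c.n_species for c in sim_ds.clades)
                        if scope == "CS"
                        else sim_ds.total_species
                    )
                    start_K = max(f.params.K, floor + 1.0)
                    fits[scope] = fit_model(
                        sim_ds,
                        f.spec,
                        n_starts=n_starts,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        opts=opts,
                        start_params=f.params.with_(K=start_K),
                        max_evals=max_evals,
                        fatol=fatol,
                        search_tail_tol=search_tail_tol,
                    )
                if not (fits["CS"].converged and fits["IW"].converged):
                    incomplete += 1
                deltas[label].append(fits["CS"].loglik - fits["IW"].loglik)
            except (ValueError, RuntimeError):
                failures[label] += 1
    total = 2 * n_reps
    if sum(failures.values()) > 0.05 * total:
        import warnings

        warnings.warn(f"bootstrap replicate failure rate above 5%: {failures}")
    d_cs = np.array(deltas["CS"])
    d_iw = np.array(deltas["IW"])
    empirical_delta = fit_cs.loglik - fit_iw.loglik
    decision = decide_model(empirical_delta, d_cs, d_iw, quantile_method)
    return BootstrapResult(
        deltas_under_cs=d_cs,
        deltas_under_iw=d_iw,
        pct5_cs=float(np.percentile(d_cs, 5.0, method=quantile_method)),
        pct95_iw=float(np.percentile(d_iw, 95.0, method=quantile_method)),
        empirical_delta=empirical_delta,
        decision=decision,
        n_failures_cs=failures["CS"],
        n_failures_iw=failures["IW"],
        n_incomplete=incomplete,
        quantile_method=quantile_method,
    )


def gof_statistics(ds: IslandDataset) -> dict:
    """Summary statistics: total species, colonist clades, largest clade, its rank.

    Rank 1 is the oldest colonization; size ties go to the earlier colonizer.
    An empty island reports zeros (rank 0).
    """
    if ds.n_clades == 0:
        return {
            "total_species": 0,
            "n_colonizations": 0,
            "largest_clade_size": 0,
            "largest_clade_rank": 0,
        }
    sizes = [c.n_species for c in ds.clades]  # clades sorted by colonization age desc
    biggest = max(sizes)
    return {
        "total_species": ds.total_species,
        "n_colonizations": ds.n_clades,
        "largest_clade_size": biggest,
        "largest_clade_rank": sizes.index(biggest) + 1,
    }


@dataclass
class GofResult:
    statistics: dict[str, np.ndarray]
    empirical: dict[str, int]
    medians: dict[str, float]
    percentiles: dict[str, float]
    n_sims: int

    def as_dict(self) -> dict:
        return {
            "empirical": self.empirical,
            "medians": self.medians,
            "percentiles": self.percentiles,
            "n_sims": self.n_sims,
        }


def gof_compare(
    ds: IslandDataset,
    fit: FitResult,
    n_sims: int,
    seed: int | None = None,
    *,
    tie_break: str = "random",
) -> GofResult:
    """Compare the data's summary statistics with simulations from a fitted model.

    Percentiles locate each empirical statistic within its simulated ensemble;
    ties are spread uniformly (``tie_break="random"``, giving calibrated
    uniform percentiles when the model is true) or split at the midpoint.
    """
    rng = np.random.default_rng(seed)
    sim = simulate_cs if fit.spec.variant == "CS" else simulate_iw
    keys = ("total_species", "n_colonizations", "largest_clade_size", "largest_clade_rank")
    ens: dict[str, list] = {k: [] for k in keys}
    for _ in range(n_sims):
        stats = gof_statistics(sim(fit.params, ds.island_age, ds.mainland_pool_M, rng=rng).dataset)
        for k in keys:
            ens[k].append(stats[k])
    arrays = {k: np.array(v) for k, v in ens.items()}
    emp = gof_statistics(ds)
    medians = {k: float(np.median(a)) for k, a in arrays.items()}
    pcts = {}
    for k, a in arrays.items():
        less = float(np.mean(a < emp[k]))
        eq = float(np.mean(a == emp[k]))
        frac = rng.uniform() if tie_break == "random" else 0.5
        pcts[k] = less + frac * eq
    return GofResult(
        statistics=arrays, empirical=emp, medians=medians, percentiles=pcts, n_sims=n_sims
    )
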