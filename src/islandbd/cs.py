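"""Clade-specific (CS) and diversity-independent (DI) likelihoods.

For full comparability with the island-wide model, the CS likelihood is the
product of island-wide likelihoods with a mainland pool of one: each observed
clade contributes the likelihood of a single-source island containing just
that clade, and the M - C mainland species that never left a surviving clade
each contribute the empty-island likelihood (computed once and scaled).  The
DI likelihood is the CS likelihood with K infinite, under which CS and IW
coincide because the per-species processes are independent.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .data import CladeRecord, IslandDataset, validate_dataset
from .likelihood import DEFAULT_OPTS, NEG_INF, LikelihoodOptions, loglik_iw
from .rates import ModelParams, diversity_cap

__all__ = ["loglik_cs", "loglik_di", "loglik_model"]


def _single_clade_dataset(ds: IslandDataset, clade: CladeRecord) -> IslandDataset:
    return IslandDataset(
        island_age=ds.island_age,
        mainland_pool_M=1,
        clades=(replace(clade, mainland_species_id=1),),
    )


def loglik_cs(
    ds: IslandDataset,
    p: ModelParams,
    opts: LikelihoodOptions = DEFAULT_OPTS,
) -> float:
    """Loglikelihood under clade-specific diversity-dependence (K per clade)."""
    violations = validate_dataset(ds)
    if violations:
        raise ValueError("invalid dataset: " + "; ".join(violations))
    cap = diversity_cap(p)
    if any(c.n_species > cap for c in ds.clades):
        return NEG_INF
    sub_opts = replace(opts, conditioning="none")
    M, C = ds.mainland_pool_M, ds.n_clades
    empty = IslandDataset(island_age=ds.island_age, mainland_pool_M=1, clades=())
    ll_empty = loglik_iw(empty, p, sub_opts)
    ll = (M - C) * ll_empty
    for clade in ds.clades:
        ll_j = loglik_iw(_single_clade_dataset(ds, clade), p, sub_opts)
        if ll_j == NEG_INF:
            return NEG_INF
        ll += ll_j
    if opts.conditioning == "colonization" and ll != NEG_INF:
        ll -= math.log1p(-math.exp(M * ll_empty))
    return ll


def loglik_di(
    ds: IslandDataset,
    p: ModelParams,
    opts: LikelihoodOptions = DEFAULT_OPTS,
) -> float:
    """Diversity-independent loglikelihood (K fixed to infinity)."""
    return loglik_cs(ds, p.with_(K=math.inf), opts)


def loglik_model(
    variant: str,
    ds: IslandDataset,
    p: ModelParams,
    opts: LikelihoodOptions = DEFAULT_OPTS,
) -> float:
    """Dispatch by model variant label ("DI", "CS" or "IW")."""
    if variant == "DI":
        return loglik_di(ds, p, opts)
    if variant == "CS":
        return loglik_cs(ds, p, opts)
    if variant == "IW":
        return loglik_iw(ds, p, opts)
    raise ValueError(f"unknown model variant {variant!r}")
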