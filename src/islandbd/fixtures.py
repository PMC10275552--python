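"""Deterministic test datasets.

``make_table1_fixture`` builds a surrogate of the Hispaniolan frog data: the
five colonist clades' colonization ages (22.09, 13.75, 11.03, 8.85, 8.43 My)
and sizes (28, 21, 3, 5, 8) are the published characteristics; the branching
ages are synthesized reproducibly (order statistics of uniforms below each
colonization age) and make no claim of matching the real, unpublished
branching times.

``make_toy_suite`` builds the small datasets used to lock the likelihood
engine: every case is simulable in bulk for the Monte-Carlo oracle, and the
pure-birth cases (mu = 0, K infinite) carry closed-form loglikelihoods derived
by elementary survival arguments (with mu = 0 nothing hidden can exist at the
present, so every factor is an explicit exponential or rate density, including
the colonization-reset survivorship of each observed lineage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import CladeRecord, IslandDataset
from .rates import ModelParams

__all__ = ["make_table1_fixture", "make_toy_suite", "ToyCase", "TABLE1_COLONIZATIONS"]

#: (colonization age My, clade size) of the five Hispaniolan colonist clades.
TABLE1_COLONIZATIONS = (
    (22.09, 28),
    (13.75, 21),
    (11.03, 3),
    (8.85, 5),
    (8.43, 8),
)


def make_table1_fixture(seed: int = 0, island_age: float = 30.0, M: int = 1000) -> IslandDataset:
    """Five-clade surrogate dataset with the published ages/sizes (seeded branchings)."""
    rng = np.random.default_rng(seed)
    clades = []
    for i, (age, size) in enumerate(TABLE1_COLONIZATIONS, start=1):
        branch = tuple(sorted(rng.uniform(0.0, age, size - 1), reverse=True)) if size > 1 else ()
        status = "endemic_clade" if size > 1 else "endemic_singleton"
        clades.append(
            CladeRecord(
                name=f"clade_{i}",
                mainland_species_id=i,
                status=status,
                colonization_age=age,
                branching_ages=branch,
            )
        )
    return IslandDataset(island_age=island_age, mainland_pool_M=M, clades=tuple(clades))


@dataclass(frozen=True)
class ToyCase:
    """A small dataset with parameters, and its exact loglikelihood if closed-form."""

    name: str
    dataset: IslandDataset
    params: ModelParams
    analytic: float | None
    bin_width: float
    description: str = ""


def _nes(name: str, mid: int, a: float) -> CladeRecord:
    return CladeRecord(name, mid, "non_endemic_singleton", a)


def _endemic(name: str, mid: int, a: float, *branch: float) -> CladeRecord:
    return CladeRecord(name, mid, "endemic_clade", a, tuple(branch))


def _pure_birth_stem_factor(T: float, a: float, M: int, g0: float, lam: float) -> float:
    """log of the pre-colonization factor for one focal founder (mu = 0, K = inf).

    Before the observed colonization at age ``a`` the founder may already hold
    a virgin singleton (earlier colonizations are erased by the reset rule
    provided the lineage neither speciates nor dies — and mu = 0 forbids
    death of anything hidden).  Summing the no-proto and live-proto routes:

        u(tau) = exp(-M g0 tau)
        v(tau) = g0 (exp(-beta tau) - exp(-alpha tau)) / (alpha - beta),
        alpha = lam + (M-1) g0,  beta = M g0,  tau = T - a,

    and the colonization density contributes g0 (u + v).
    """
    tau = T - a
    alpha = lam + (M - 1) * g0
    beta = M * g0
    u = math.exp(-beta * tau)
    if abs(alpha - beta) < 1e-12:
        v = g0 * tau * math.exp(-beta * tau)
    else:
        v = g0 * (math.exp(-beta * tau) - math.exp(-alpha * tau)) / (alpha - beta)
    return math.log(g0) + math.log(u + v)


def make_toy_suite(
    T: float = 5.0,
    M: int = 10,
    g0: float = 0.01,
    lam: float = 0.3,
    mu: float = 0.2,
) -> dict[str, ToyCase]:
    """Named <=3-event datasets spanning (mu=0, mu>0) x (K finite, inf) x 0/1/2 branchings."""
    pb = ModelParams(lambda_c0=lam, mu=0.0, K=math.inf, gamma0=g0, lambda_a=0.0)
    bd = ModelParams(lambda_c0=lam, mu=mu, K=math.inf, gamma0=g0, lambda_a=0.0)
    bdk = ModelParams(lambda_c0=lam, mu=mu, K=4.0, gamma0=g0 * 3, lambda_a=0.0)
    suite: dict[str, ToyCase] = {}

    def add(name: str, ds: IslandDataset, p: ModelParams, analytic, bw: float, desc: str):
        suite[name] = ToyCase(name, ds, p, analytic, bw, desc)

    # -- pure birth (mu = 0, K = inf): closed forms ---------------------------
    empty = IslandDataset(T, M, ())
    add("empty_pure_birth", empty, pb, -M * g0 * T, 0.0, "no colonization may stick when mu=0")

    a = 2.0
    ds1 = IslandDataset(T, M, (_nes("c1", 1, a),))
    # the observed singleton must stay non-endemic: no speciation on (0, a)
    ll1 = _pure_birth_stem_factor(T, a, M, g0, lam) - (lam + M * g0) * a
    add("single_colonist_pure_birth", ds1, pb, ll1, 0.4, "last colonization at a; others never")

    a, b = 3.0, 1.0
    ds2 = IslandDataset(T, M, (_endemic("c1", 1, a, b),))
    ll2 = (
        _pure_birth_stem_factor(T, a, M, g0, lam)
        + math.log(lam)
        - (lam + M * g0) * (a - b)
        - (2 * lam + M * g0) * b
    )
    add("endemic_pair_pure_birth", ds2, pb, ll2, 0.4, "one colonization + one branching")

    a1, a2 = 3.5, 1.5
    ds3 = IslandDataset(T, M, (_nes("c1", 1, a1), _nes("c2", 2, a2)))
    # with K = inf and mu = 0 the process factorizes over mainland species
    ll3 = sum(
        _pure_birth_stem_factor(T, aa, 1, g0, lam) - (lam + g0) * aa for aa in (a1, a2)
    ) - (M - 2) * g0 * T
    add("two_colonists_pure_birth", ds3, pb, ll3, 0.4, "two independent colonists")

    a, b1, b2 = 3.0, 1.8, 0.8
    ds4 = IslandDataset(T, M, (_endemic("c1", 1, a, b1, b2),))
    ll4 = (
        _pure_birth_stem_factor(T, a, M, g0, lam)
        + math.log(lam)
        + math.log(2 * lam)
        - (lam + M * g0) * (a - b1)
        - (2 * lam + M * g0) * (b1 - b2)
        - (3 * lam + M * g0) * b2
    )
    add("endemic_triple_pure_birth", ds4, pb, ll4, 0.4, "two branchings lock the k_j factor")

    # -- with extinction: oracle-only -----------------------------------------
    ds5 = IslandDataset(T, M, (_nes("c1", 1, 2.0),))
    add("single_colonist_bd", ds5, bd, None, 0.5, "mu>0, K=inf")

    ds6 = IslandDataset(T, M, (_endemic("c1", 1, 3.0, 1.2),))
    add("endemic_pair_bd", ds6, bd, None, 0.5, "mu>0, K=inf, one branching")

    ds7 = IslandDataset(T, M, (_endemic("c1", 1, 3.0, 1.5, 0.6),))
    add("endemic_triple_capped", ds7, bdk, None, 0.5, "mu>0, finite K, two branchings")

    ds8 = IslandDataset(T, M, (CladeRecord("c1", 1, "endemic_singleton", 2.5),))
    add(
        "endemic_singleton_bd",
        ds8,
        bd,
        None,
        0.5,
        "endemicity via an in-situ speciation whose sister died",
    )

    ana = ModelParams(lambda_c0=0.1, mu=0.1, K=math.inf, gamma0=g0, lambda_a=0.4)
    ds9 = IslandDataset(
        T,
        M,
        (
            CladeRecord("c1", 1, "endemic_singleton", 3.0),
            _nes("c2", 2, 1.5),
        ),
    )
    add(
        "singletons_anagenesis",
        ds9,
        ana,
        None,
        0.5,
        "anagenesis flip plus non-endemic survivorship under lambda_a > 0",
    )

    return suite
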