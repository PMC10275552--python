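"""Model parameters and diversity-dependent per-capita rate functions.

The island assembly process has five rates: cladogenesis (in-situ speciation,
``lambda_c0`` at zero diversity), extinction (``mu``), colonization from the
mainland (``gamma0`` per mainland species at zero diversity), anagenesis
(``lambda_a``, divergence of a non-endemic island population from its mainland
ancestor) and a carrying capacity ``K`` at which the linearly declining
cladogenesis and colonization rates hit zero.  Extinction and anagenesis are
diversity-independent.

The same rate functions serve the stochastic simulator and the ODE
likelihoods; what differs between model variants is only the scope of the
diversity count ``N`` (per colonist clade under CS, whole island under IW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ModelParams",
    "ModelSpec",
    "clado_rate",
    "colonization_rate",
    "diversity_cap",
]

_VARIANTS = ("DI", "CS", "IW")


@dataclass(frozen=True)
class ModelParams:
    """The five rate parameters of the birth-death-colonization model.

    Parameters
    ----------
    lambda_c0 : float
        Cladogenesis rate at zero diversity, per species per My.
    mu : float
        Extinction rate, per species per My (diversity-independent).
    K : float
        Carrying capacity in species; ``math.inf`` disables the feedback.
        Need not be an integer.
    gamma0 : float
        Colonization rate at zero diversity, per mainland species per My.
    lambda_a : float
        Anagenesis rate, per non-endemic island species per My
        (diversity-independent).
    """

    lambda_c0: float
    mu: float
    K: float
    gamma0: float
    lambda_a: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_c0", "mu", "gamma0", "lambda_a"):
            v = getattr(self, name)
            if not (v >= 0.0) or math.isinf(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (self.K > 0.0):
            raise ValueError(f"K must be positive (or inf), got {self.K!r}")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {
            "lambda_c0": self.lambda_c0,
            "mu": self.mu,
            "K": self.K,
            "gamma0": self.gamma0,
            "lambda_a": self.lambda_a,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        K = d["K"]
        if isinstance(K, str):
            K = math.inf if K.lower() in ("inf", "infinity") else float(K)
        return cls(
            lambda_c0=float(d["lambda_c0"]),
            mu=float(d["mu"]),
            K=K,
            gamma0=float(d["gamma0"]),
            lambda_a=float(d.get("lambda_a", 0.0)),
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which of the five fitted model variants is meant.

    ``variant`` is one of ``"DI"`` (diversity-independent, K fixed infinite),
    ``"CS"`` (clade-specific carrying capacity) or ``"IW"`` (island-wide
    carrying capacity).  ``anagenesis_fixed_zero`` pins lambda_a at 0 (the
    "noA" variants).
    """

    variant: str
    anagenesis_fixed_zero: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")

    @property
    def label(self) -> str:
        if self.variant == "DI":
            return "DI"
        return f"DD-{self.variant}" + ("-noA" if self.anagenesis_fixed_zero else "")

    @property
    def df(self) -> int:
        """Number of free parameters (DI: lambda_c0, mu, gamma0, lambda_a)."""
        n = 5
        if self.variant == "DI":
            n -= 1  # K fixed to infinity
        if self.anagenesis_fixed_zero:
            n -= 1
        return n


def clado_rate(N: float, p: ModelParams) -> float:
    """Per-capita cladogenesis rate at diversity ``N``: max(0, lambda_c0 (1 - N/K))."""
    if math.isinf(p.K):
        return p.lambda_c0
    return max(0.0, p.lambda_c0 * (1.0 - N / p.K))


def colonization_rate(N: float, p: ModelParams) -> float:
    """Per-mainland-species colonization rate at diversity ``N``."""
    if math.isinf(p.K):
        return p.gamma0
    return max(0.0, p.gamma0 * (1.0 - N / p.K))


def diversity_cap(p: ModelParams) -> float:
    """Smallest integer diversity at which colonization and cladogenesis stop.

    For finite non-integer K this is ceil(K); for integer K it is K itself
    (the linear rates are exactly zero there); infinite K gives ``math.inf``.
    """
    if math.isinf(p.K):
        return math.inf
    return float(math.ceil(p.K))
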