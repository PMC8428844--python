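"""Trait space, tradeoff constraint, and uptake/growth kernels.

A consumer phenotype is its metabolic allocation strategy
``alpha = (alpha_1, ..., alpha_p)``: the per-capita metabolic effort invested
in taking up each of ``p`` substitutable resources.  Finite cellular resources
impose a power-law budget on permissible strategies,

    sum_j alpha_j ** gamma_j  =  E,

with all ``gamma_j > 0`` and budget ``E > 0``.  The exponent controls the
curvature of the tradeoff surface: ``gamma < 1`` concave, ``gamma > 1``
convex, ``gamma = 1`` the linear simplex.  Resource uptake saturates with
concentration through a Monod response ``r(c) = c / (K + c)``, and the
per-capita birth rate of a consumer equals its total uptake
``sum_j alpha_j**q_j * r_j(c_j)`` (the optional uptake exponent ``q_j``
transfers non-linearity from the budget into the uptake rates; see
:func:`reparametrize`).

Everything downstream -- chemostat and serial-dilution ecology, adaptive
dynamics, the evolution engine -- builds on the handful of kernels defined
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TradeoffSpec",
    "Phenotype",
    "EnvironmentSpec",
    "CommunityState",
    "monod_uptake",
    "tradeoff_value",
    "project_to_constraint",
    "growth_rate",
    "reparametrize",
    "CONSTRAINT_TOL",
]

#: maximum allowed |sum_j alpha_j**gamma_j - E| for a constructed phenotype
CONSTRAINT_TOL = 1e-10


def _vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TradeoffSpec:
    """The constraint manifold ``sum_j alpha_j**gamma_j = E``.

    ``gamma`` may be a scalar (broadcast to every direction) or a length-p
    vector of per-direction exponents; ``budget`` is the total budget E.
    """

    gamma: np.ndarray = 1.0
    budget: float = 1.0

    def __post_init__(self):
        g = _vector(self.gamma, "gamma")
        if np.any(g <= 0):
            raise ValueError("all tradeoff exponents gamma must be positive")
        if not self.budget > 0:
            raise ValueError("budget E must be positive")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "budget", float(self.budget))

    @property
    def is_uniform(self) -> bool:
        return self.gamma.size == 1 or bool(np.all(self.gamma == self.gamma[0]))

    def gammas(self, p: int) -> np.ndarray:
        """Exponent vector broadcast to ``p`` directions."""
        if self.gamma.size == 1:
            return np.full(p, self.gamma[0])
        if self.gamma.size != p:
            raise ValueError(
                f"gamma has {self.gamma.size} components, expected {p}"
            )
        return self.gamma


@dataclass(frozen=True, eq=False)
class Phenotype:
    """An allocation strategy: a non-negative vector on the tradeoff surface."""

    alpha: np.ndarray

    def __post_init__(self):
        a = _vector(self.alpha, "alpha")
        if np.any(a < 0):
            raise ValueError("allocation components must be non-negative")
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "alpha", a)

    @property
    def p(self) -> int:
        return self.alpha.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Phenotype) and np.array_equal(
            self.alpha, other.alpha
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phenotype({np.array2string(self.alpha, precision=6)})"


@dataclass(frozen=True)
class EnvironmentSpec:
    """Abiotic parameters of the chemostat (and the Monod constants shared
    with the serial-dilution protocol).

    supply          resource supply rates s_j
    monod_K         half-saturation constants K_j (> 0)
    decay           abiotic resource decay rates mu_j
    death_rate      per-capita consumer death rate delta
    uptake_exponent q_j; uptake and consumption use alpha_j**q_j (default 1)
    """

    supply: np.ndarray
    monod_K: np.ndarray
    decay: np.ndarray
    death_rate: float = 0.0
    uptake_exponent: np.ndarray | None = None

    def __post_init__(self):
        s = _vector(self.supply, "supply")
        p = s.size
        K = np.broadcast_to(_vector(self.monod_K, "monod_K"), (p,)).astype(float)
        mu = np.broadcast_to(_vector(self.decay, "decay"), (p,)).astype(float)
        q = (
            np.ones(p)
            if self.uptake_exponent is None
            else np.broadcast_to(
                _vector(self.uptake_exponent, "uptake_exponent"), (p,)
            ).astype(float)
        )
        if np.any(s < 0):
            raise ValueError("supply rates must be non-negative")
        if np.any(K <= 0):
            raise ValueError("Monod constants must be positive")
        if np.any(mu < 0):
            raise ValueError("decay rates must be non-negative")
        if self.death_rate < 0:
            raise ValueError("death rate must be non-negative")
        if np.any(q <= 0):
            raise ValueError("uptake exponents must be positive")
        for name, arr in (
            ("supply", s),
            ("monod_K", K),
            ("decay", mu),
            ("uptake_exponent", q),
        ):
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "death_rate", float(self.death_rate))

    @property
    def p(self) -> int:
        return self.supply.size

    @classmethod
    def symmetric(
        cls,
        p: int = 3,
        supply: float = 1.0,
        monod_K: float = 1.0,
        decay: float = 0.1,
        death_rate: float = 0.25,
        uptake_exponent: float = 1.0,
    ) -> "EnvironmentSpec":
        """Symmetric chemostat with s_j = supply, K_j = monod_K, mu_j = decay.

        The defaults are the standard parameterization s_j = 1,
        mu_j * K_j = 0.1 (realized as K_j = 1, mu_j = 0.1) and delta = 0.25.
        """
        return cls(
            supply=np.full(p, supply),
            monod_K=np.full(p, monod_K),
            decay=np.full(p, decay),
            death_rate=death_rate,
            uptake_exponent=np.full(p, uptake_exponent),
        )

    def replace(self, **kw) -> "EnvironmentSpec":
        d = dict(
            supply=self.supply,
            monod_K=self.monod_K,
            decay=self.decay,
            death_rate=self.death_rate,
            uptake_exponent=self.uptake_exponent,
        )
        d.update(kw)
        return EnvironmentSpec(**d)


@dataclass
class CommunityState:
    """A multi-strain community: (phenotype, density) pairs plus resources."""

    strains: list[tuple[Phenotype, float]]
    concentrations: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.concentrations = _vector(self.concentrations, "concentrations")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        for _, n in self.strains:
            if n < 0:
                raise ValueError("densities must be non-negative")

    @property
    def p(self) -> int:
        return self.concentrations.size

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def alpha_matrix(self) -> np.ndarray:
        """(n_strains, p) matrix of allocation vectors."""
        if not self.strains:
            return np.empty((0, self.p))
        return np.array([ph.alpha for ph, _ in self.strains])

    def densities(self) -> np.ndarray:
        return np.array([n for _, n in self.strains])

    def total_density(self) -> float:
        return float(sum(n for _, n in self.strains))

    def mean_phenotype(self) -> np.ndarray:
        """Density-weighted mean allocation vector (not on the surface in
        general; used as a summary statistic)."""
        if not self.strains:
            raise ValueError("empty community has no mean phenotype")
        n = self.densities()
        return (self.alpha_matrix() * n[:, None]).sum(axis=0) / n.sum()

    def copy(self) -> "CommunityState":
        return CommunityState(
            strains=list(self.strains),
            concentrations=self.concentrations.copy(),
            time=self.time,
        )


def monod_uptake(c, K):
    """Monod saturating uptake response ``r(c) = c / (K + c)``.

    Accepts scalars or arrays (broadcast); strictly increasing in ``c`` and
    bounded above by 1.
    """
    c = np.asarray(c, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(K <= 0):
        raise ValueError("Monod constant must be positive")
    out = c / (K + c)
    return float(out) if out.ndim == 0 else out


def tradeoff_value(alpha, spec: TradeoffSpec) -> float:
    """Budget expenditure ``sum_j alpha_j**gamma_j`` of an allocation vector.

    ``0**gamma`` is 0 for every ``gamma > 0``, so boundary strategies are
    handled exactly.
    """
    a = _vector(alpha, "alpha")
    if np.any(a < 0):
        raise ValueError("allocation components must be non-negative")
    g = spec.gammas(a.size)
    return float(np.sum(a**g))


def project_to_constraint(alpha_raw, spec: TradeoffSpec) -> Phenotype:
    """Radially rescale a raw non-negative vector onto the tradeoff surface.

    Returns ``lambda * alpha_raw`` with the scalar ``lambda > 0`` solving
    ``sum_j (lambda * alpha_j)**gamma_j = E``.  For uniform gamma the closed
    form ``lambda = (E / sum alpha**gamma)**(1/gamma)`` is used; otherwise
    the (strictly monotone) scalar equation is bracketed and solved to
    machine precision.
    """
    a = _vector(alpha_raw, "alpha_raw")
    if np.any(a < 0):
        raise ValueError("allocation components must be non-negative")
    if not np.any(a > 0):
        raise ValueError("cannot project the all-zero vector")
    g = spec.gammas(a.size)
    E = spec.budget
    if spec.is_uniform:
        gam = g[0]
        lam = (E / np.sum(a**gam)) ** (1.0 / gam)
        return Phenotype(lam * a)

    mask = a > 0

    def residual(lam: float) -> float:
        return float(np.sum((lam * a[mask]) ** g[mask]) - E)

    lo = hi = 1.0
    while residual(lo) > 0:
        lo /= 2.0
    while residual(hi) < 0:
        hi *= 2.0
    lam = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    out = lam * a
    # brentq already leaves |residual| at rounding level; verify the contract
    assert abs(tradeoff_value(out, spec) - E) <= 1e-12 * max(1.0, E)
    return Phenotype(out)


def _alpha_of(phenotype) -> np.ndarray:
    return phenotype.alpha if isinstance(phenotype, Phenotype) else _vector(
        phenotype, "alpha"
    )


def effective_alpha(phenotype, env: EnvironmentSpec) -> np.ndarray:
    """``alpha_j ** q_j``: the allocation as it enters uptake and consumption."""
    a = _alpha_of(phenotype)
    return a**env.uptake_exponent


def growth_rate(phenotype, c, env: EnvironmentSpec) -> float:
    """Per-capita growth rate ``sum_j alpha_j**q_j * r_j(c_j) - delta``."""
    r = monod_uptake(c, env.monod_K)
    return float(effective_alpha(phenotype, env) @ np.atleast_1d(r)) - env.death_rate


def reparametrize(
    phenotype: Phenotype, spec: TradeoffSpec
) -> tuple[Phenotype, TradeoffSpec, np.ndarray]:
    """Map a non-linear-budget model onto the linear-budget representation.

    For uniform gamma, ``beta_j = alpha_j**gamma`` lies on the linear surface
    ``sum beta_j = E`` and, with uptake exponents ``q' = 1/gamma``, has the
    identical per-capita growth rate for every resource state:
    ``sum beta_j**(1/gamma) r_j = sum alpha_j r_j``.  The two representations
    therefore generate the same community dynamics; the non-linearity has
    been transferred from the budget into the uptake rates.

    Returns ``(Phenotype(beta), TradeoffSpec(1, E), q')``.
    """
    if not spec.is_uniform:
        raise NotImplementedError(
            "reparametrization is defined for a uniform tradeoff exponent"
        )
    a = phenotype.alpha
    gam = float(spec.gamma[0])
    beta = a**gam
    qprime = np.full(a.size, 1.0 / gam)
    return Phenotype(beta), TradeoffSpec(gamma=1.0, budget=spec.budget), qprime
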