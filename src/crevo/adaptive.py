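"""Adaptive-dynamics analytics on the tradeoff surface.

Invasion fitness of a rare mutant strategy alpha' against a resident alpha
at its ecological equilibrium, the selection gradient and its singular
(equilibrium) point, and the two stability questions that decide the fate of
an evolving monomorphic population:

* convergence stability -- do eigenvalues of the Jacobian of the
  adaptive-dynamics flow at the singular point have negative real parts?
  (If so, a monomorphic population is attracted to it.)
* evolutionary stability -- is the invasion-fitness Hessian, restricted to
  the tangent space of the constraint surface, negative definite (an ESS,
  evolution halts) or does it have a positive direction (disruptive
  selection: an evolutionary branching point)?

For vanishing resource decay (mu = 0) the resident equilibrium is available
in closed form, which makes invasion fitness itself closed form,

    f(alpha'; alpha) = sum_j alpha'_j**q_j r_j* - delta,
    r_j* = s_j / (n* alpha_j**q_j),  n* = sum_j s_j / delta,

and all derivative quantities are computed by finite differences of this
exact expression in an orthonormal tangent basis.  The qualitative outcome
is governed by the curvature of the tradeoff surface: the tangent Hessian
eigenvalues carry the sign of (1 - gamma_j), so gamma < 1 marks a branching
point, gamma > 1 an ESS, and gamma = 1 exact neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemostat import (
    IntegrationControl,
    integrate_to_stationarity,
    resident_equilibrium_mu0,
)
from .core import (
    CommunityState,
    EnvironmentSpec,
    Phenotype,
    TradeoffSpec,
    _vector,
    effective_alpha,
    growth_rate,
    project_to_constraint,
)

__all__ = [
    "SingularPointReport",
    "BoundaryResidentError",
    "singular_point",
    "invasion_fitness",
    "selection_gradient",
    "classify_singular_point",
    "tangent_basis",
]


class BoundaryResidentError(ValueError):
    """Tangent-space analytics need a strictly interior resident: the
    constraint normal gamma_j alpha_j**(gamma_j - 1) diverges on the boundary
    when gamma_j < 1."""


@dataclass(frozen=True)
class SingularPointReport:
    """Stability summary at the singular strategy alpha*."""

    alpha_star: Phenotype
    jacobian_eigs: np.ndarray   # adaptive-dynamics Jacobian (convergence)
    hessian_eigs: np.ndarray    # tangent-space invasion-fitness Hessian
    hessian: np.ndarray
    classification: str         # branching_point | ess_endpoint | neutral | mixed
    per_direction: np.ndarray   # per-resource branching flags
    tolerance: float


def singular_point(supply, spec: TradeoffSpec) -> Phenotype:
    """The unique singular strategy alpha* of the mu = 0 adaptive dynamics.

    The selection gradient vanishes where the fitness gradient is parallel
    to the constraint normal, which gives in closed form

        alpha_j*^gamma_j = E (s_j / gamma_j) / sum_k (s_k / gamma_k).

    For a uniform exponent this reduces to alpha_j* = (E s_j / sum_k s_k)**(1/gamma),
    the supply-share rule: with E = 1, each resource receives a budget share
    equal to its share of total supply.
    """
    s = _vector(supply, "supply")
    if np.any(s < 0):
        raise ValueError("supply rates must be non-negative")
    if not np.any(s > 0):
        raise ValueError("at least one supply rate must be positive")
    g = spec.gammas(s.size)
    w = s / g
    shares = spec.budget * w / np.sum(w)
    return Phenotype(shares ** (1.0 / g))


def resident_uptake(
    resident: Phenotype,
    env: EnvironmentSpec,
    ctrl: IntegrationControl | None = None,
) -> np.ndarray:
    """Equilibrium uptake factors r_j(c_j*) set by a monomorphic resident.

    Closed form when mu = 0; otherwise the resident is equilibrated
    numerically from a standard initial condition.
    """
    if np.all(env.decay == 0):
        return resident_equilibrium_mu0(resident, env).uptake
    ctrl = ctrl or IntegrationControl.for_environment(env)
    n0 = float(np.sum(env.supply)) / max(env.death_rate, 1e-3)
    state = CommunityState(
        strains=[(resident, n0)],
        concentrations=env.monod_K.copy(),
        time=0.0,
    )
    eq = integrate_to_stationarity(state, env, ctrl, residual=1e-9)
    c = eq.concentrations
    return c / (env.monod_K + c)


def invasion_fitness(
    mutant: Phenotype,
    resident: Phenotype,
    env: EnvironmentSpec,
    ctrl: IntegrationControl | None = None,
    _uptake: np.ndarray | None = None,
) -> float:
    """Per-capita growth rate of a rare mutant at the resident equilibrium."""
    r = resident_uptake(resident, env, ctrl) if _uptake is None else _uptake
    return float(effective_alpha(mutant, env) @ r) - env.death_rate


def tangent_basis(alpha: np.ndarray, spec: TradeoffSpec) -> np.ndarray:
    """Orthonormal basis (p x (p-1)) of the constraint tangent space.

    The normal is the constraint gradient (gamma_j alpha_j**(gamma_j - 1))_j;
    the basis is completed deterministically by a Householder reflection
    mapping e_1 onto the unit normal.
    """
    a = np.asarray(alpha, dtype=float)
    p = a.size
    g = spec.gammas(p)
    if np.any((a <= 0) & (g < 1)):
        raise BoundaryResidentError(
            "constraint normal undefined at the boundary for gamma < 1"
        )
    normal = g * a ** (g - 1.0)
    n_hat = normal / np.linalg.norm(normal)
    v = n_hat.copy()
    v[0] += np.copysign(1.0, n_hat[0] if n_hat[0] != 0 else 1.0)
    H = np.eye(p) - 2.0 * np.outer(v, v) / (v @ v)
    return H[:, 1:]


def _retract(alpha: np.ndarray, spec: TradeoffSpec) -> Phenotype:
    return project_to_constraint(np.maximum(alpha, 0.0), spec)


def selection_gradient(
    resident: Phenotype,
    env: EnvironmentSpec,
    spec: TradeoffSpec,
    step: float = 1e-6,
    ctrl: IntegrationControl | None = None,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """Invasion-fitness gradient along the constraint surface at the resident.

    Central finite differences of f(mutant; resident) in the mutant, with the
    mutant retracted onto the surface, expressed in an orthonormal tangent
    basis at the resident.  Vanishes (to O(step**2)) exactly at the singular
    point.
    """
    a = resident.alpha
    if np.any(a == 0):
        raise BoundaryResidentError(
            "selection gradient requires a strictly interior resident"
        )
    U = tangent_basis(a, spec) if basis is None else basis
    r_star = resident_uptake(resident, env, ctrl)
    grad = np.empty(U.shape[1])
    for i in range(U.shape[1]):
        fp = invasion_fitness(
            _retract(a + step * U[:, i], spec), resident, env, _uptake=r_star
        )
        fm = invasion_fitness(
            _retract(a - step * U[:, i], spec), resident, env, _uptake=r_star
        )
        grad[i] = (fp - fm) / (2.0 * step)
    return grad


def _mutant_hessian(
    alpha_star: np.ndarray,
    U: np.ndarray,
    env: EnvironmentSpec,
    spec: TradeoffSpec,
    r_star: np.ndarray,
    step: float,
) -> np.ndarray:
    """Tangent-space Hessian of invasion fitness in the mutant at alpha*."""
    resident = Phenotype(alpha_star)

    def f(u: np.ndarray) -> float:
        mutant = _retract(alpha_star + U @ u, spec)
        return invasion_fitness(mutant, resident, env, _uptake=r_star)

    k = U.shape[1]
    H = np.empty((k, k))
    f0 = f(np.zeros(k))
    h = step
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(ei) - 2.0 * f0 + f(-ei)) / h**2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
            ) / (4.0 * h**2)
    return 0.5 * (H + H.T)


def _gradient_jacobian(
    alpha_star: np.ndarray,
    U: np.ndarray,
    env: EnvironmentSpec,
    spec: TradeoffSpec,
    step: float,
    ctrl: IntegrationControl | None,
) -> np.ndarray:
    """Jacobian of the selection gradient w.r.t. the resident (tangent
    coordinates fixed at alpha*); its eigenvalues decide convergence
    stability of the adaptive-dynamics flow."""
    k = U.shape[1]
    J = np.empty((k, k))
    for j in range(k):
        dp = _retract(alpha_star + step * U[:, j], spec)
        dm = _retract(alpha_star - step * U[:, j], spec)
        gp = selection_gradient(dp, env, spec, ctrl=ctrl, basis=U)
        gm = selection_gradient(dm, env, spec, ctrl=ctrl, basis=U)
        J[:, j] = (gp - gm) / (2.0 * step)
    return J


def classify_singular_point(
    env: EnvironmentSpec,
    spec: TradeoffSpec,
    hessian_step: float = 1e-3,
    jacobian_step: float = 1e-4,
    ctrl: IntegrationControl | None = None,
) -> SingularPointReport:
    """Locate and classify the singular strategy.

    Classification rule on the tangent-space Hessian eigenvalues with
    tolerance tol = 1e-8 * delta: all < -tol -> ``ess_endpoint``; any > +tol
    -> ``branching_point``; all within +/-tol -> ``neutral``; otherwise
    ``mixed``.  ``per_direction[j]`` flags disruptive curvature along the
    (tangent-projected) direction of resource j, which for heterogeneous
    exponents picks out exactly the directions with gamma_j < 1.
    """
    astar = singular_point(env.supply, spec)
    a = astar.alpha
    U = tangent_basis(a, spec)
    r_star = resident_uptake(astar, env, ctrl)
    H = _mutant_hessian(a, U, env, spec, r_star, hessian_step)
    h_eigs = np.linalg.eigvalsh(H)
    J = _gradient_jacobian(a, U, env, spec, jacobian_step, ctrl)
    j_eigs = np.linalg.eigvals(J)

    tol = 1e-8 * (env.death_rate if env.death_rate > 0 else 1.0)
    if np.all(h_eigs < -tol):
        label = "ess_endpoint"
    elif np.any(h_eigs > tol):
        label = "branching_point"
    elif np.all(np.abs(h_eigs) <= tol):
        label = "neutral"
    else:
        label = "mixed"

    # directional curvature along each resource axis projected onto the
    # tangent space: positive -> disruptive selection along that direction
    resident = astar
    P = U @ U.T
    flags = np.zeros(env.p, dtype=bool)
    for j in range(env.p):
        d = P @ np.eye(env.p)[:, j]
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        d /= nrm
        h = hessian_step
        fp = invasion_fitness(_retract(a + h * d, spec), resident, env, _uptake=r_star)
        fm = invasion_fitness(_retract(a - h * d, spec), resident, env, _uptake=r_star)
        f0 = invasion_fitness(astar, resident, env, _uptake=r_star)
        flags[j] = (fp - 2.0 * f0 + fm) / h**2 > tol

    return SingularPointReport(
        alpha_star=astar,
        jacobian_eigs=j_eigs,
        hessian_eigs=h_eigs,
        hessian=H,
        classification=label,
        per_direction=flags,
        tolerance=tol,
    )
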