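"""Chemostat ecology: multi-strain resource-consumer ODEs and equilibria.

The ecological state is the stacked vector of strain densities ``n_a`` and
resource concentrations ``c_j``, evolving as

    dc_j/dt = s_j - (sum_a n_a alpha_aj**q_j) r_j(c_j) - mu_j c_j
    dn_a/dt = (sum_j alpha_aj**q_j r_j(c_j) - delta) n_a

with Monod uptake r_j(c) = c/(K_j + c).  Integration uses an adaptive
stiff-capable solver (LSODA); non-negativity is maintained by evaluating the
Monod response on ``max(c, 0)`` mid-step and clipping stray negatives at
checkpoint boundaries, where strains below the extinction threshold are also
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import odeint

from .core import (
    CommunityState,
    EnvironmentSpec,
    Phenotype,
    monod_uptake,
)

__all__ = [
    "IntegrationControl",
    "IntegrationFailure",
    "InfeasibleEquilibriumError",
    "derivatives",
    "integrate",
    "integrate_to_stationarity",
    "stationarity_residual",
    "resident_equilibrium_mu0",
    "Mu0Equilibrium",
]


@dataclass(frozen=True)
class IntegrationControl:
    """Solver and bookkeeping knobs shared by all dynamics runs.

    ``extinction_threshold`` is an absolute density; strains below it are
    removed at checkpoint boundaries.  Use :meth:`for_environment` to scale
    it relative to the characteristic community density sum(s)/delta.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_time: float = 1e6
    extinction_threshold: float = 1e-6
    checkpoint_interval: float = 10.0

    def __post_init__(self):
        if not (0 < self.rel_tol <= 1e-3 and 0 < self.abs_tol <= 1e-3):
            raise ValueError("tolerances must lie in (0, 1e-3]")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be positive")

    @classmethod
    def for_environment(
        cls, env: EnvironmentSpec, rel_extinction: float = 1e-6, **kw
    ) -> "IntegrationControl":
        """Control with extinction threshold relative to n* ~ sum(s)/delta."""
        scale = (
            float(np.sum(env.supply)) / env.death_rate
            if env.death_rate > 0
            else 1.0
        )
        return cls(extinction_threshold=rel_extinction * scale, **kw)


class IntegrationFailure(RuntimeError):
    """Solver failure; carries the last successfully reached state."""

    def __init__(self, message: str, last_state: CommunityState):
        super().__init__(message)
        self.last_state = last_state


class InfeasibleEquilibriumError(RuntimeError):
    """Monomorphic mu=0 equilibrium would need uptake factors r* >= 1."""


def _rhs_factory(A: np.ndarray, env: EnvironmentSpec):
    """Right-hand side over y = [n_1..n_S, c_1..c_p].

    ``A`` is the (S, p) matrix of effective allocations alpha**q, applied in
    both the consumption and the growth term so biomass bookkeeping stays
    consistent.
    """
    S = A.shape[0]
    s, K, mu, delta = env.supply, env.monod_K, env.decay, env.death_rate

    def rhs(t, y):
        n = y[:S]
        c = np.maximum(y[S:], 0.0)
        r = c / (K + c)
        dn = n * (A @ r - delta)
        dc = s - (A.T @ n) * r - mu * c
        return np.concatenate((dn, dc))

    return rhs


def derivatives(
    state: CommunityState, env: EnvironmentSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous (dn/dt, dc/dt) of the chemostat equations."""
    A = state.alpha_matrix() ** env.uptake_exponent
    n = state.densities()
    r = monod_uptake(state.concentrations, env.monod_K)
    dn = n * (A @ r - env.death_rate)
    dc = env.supply - (A.T @ n) * r - env.decay * state.concentrations
    return dn, dc


def stationarity_residual(state: CommunityState, env: EnvironmentSpec) -> float:
    """max over strains/resources of |dn/dt|/n and |dc/dt|."""
    dn, dc = derivatives(state, env)
    n = state.densities()
    rn = np.abs(dn) / np.maximum(n, 1e-300) if n.size else np.zeros(0)
    return float(max(rn.max(initial=0.0), np.abs(dc).max(initial=0.0)))


def _advance(
    state: CommunityState,
    env: EnvironmentSpec,
    ctrl: IntegrationControl,
    duration: float,
    chunk: float,
) -> CommunityState:
    """Integrate for `duration`, culling extinct strains every `chunk`."""
    phenos = [ph for ph, _ in state.strains]
    n = state.densities()
    c = state.concentrations.copy()
    t_done = 0.0
    while t_done < duration - 1e-12 * max(duration, 1.0):
        dt = min(chunk, duration - t_done)
        A = (
            np.array([ph.alpha for ph in phenos]) ** env.uptake_exponent
            if phenos
            else np.empty((0, env.p))
        )
        rhs = _rhs_factory(A, env)
        y0 = np.concatenate((n, c))
        # odeint wraps the same LSODA core as solve_ivp's "LSODA" but
        # through the leak-free odepack interface; with thousands of short
        # integrations per evolution run this matters
        out, info = odeint(
            rhs,
            y0,
            [0.0, dt],
            tfirst=True,
            rtol=ctrl.rel_tol,
            atol=ctrl.abs_tol,
            mxstep=1_000_000,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationFailure(
                f"LSODA failed: {info['message']}",
                CommunityState(
                    strains=list(zip(phenos, n)),
                    concentrations=np.maximum(c, 0.0),
                    time=state.time + t_done,
                ),
            )
        y = out[-1]
        n = np.maximum(y[: len(phenos)], 0.0)
        c = np.maximum(y[len(phenos):], 0.0)
        keep = n >= ctrl.extinction_threshold
        if not keep.all():
            phenos = [ph for ph, k in zip(phenos, keep) if k]
            n = n[keep]
        t_done += dt
    return CommunityState(
        strains=list(zip(phenos, map(float, n))),
        concentrations=c,
        time=state.time + duration,
    )


def integrate(
    state: CommunityState,
    env: EnvironmentSpec,
    ctrl: IntegrationControl,
    duration: float,
) -> CommunityState:
    """Advance the community by ``duration`` chemostat time units."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return _advance(state, env, ctrl, duration, ctrl.checkpoint_interval)


def integrate_to_stationarity(
    state: CommunityState,
    env: EnvironmentSpec,
    ctrl: IntegrationControl,
    residual: float = 1e-8,
    max_chunk: float = 2000.0,
) -> CommunityState:
    """Integrate until the stationarity residual drops below ``residual``.

    Checkpoint chunks double geometrically (transients shorten as the system
    settles), capped at ``max_chunk``; gives up at ``ctrl.max_time``.
    """
    cur = state
    chunk = ctrl.checkpoint_interval
    elapsed = 0.0
    while elapsed < ctrl.max_time:
        dt = min(chunk, ctrl.max_time - elapsed)
        cur = _advance(cur, env, ctrl, dt, dt)
        elapsed += dt
        if stationarity_residual(cur, env) < residual:
            return cur
        chunk = min(chunk * 2.0, max_chunk)
    return cur


class Mu0Equilibrium(NamedTuple):
    """Closed-form monomorphic chemostat equilibrium at mu = 0."""

    density: float       # n* = sum_j s_j / delta
    uptake: np.ndarray   # r_j* = s_j / (n* alpha_j**q_j)
    concentration: np.ndarray  # c_j* = K_j r_j* / (1 - r_j*)


def resident_equilibrium_mu0(
    phenotype: Phenotype, env: EnvironmentSpec
) -> Mu0Equilibrium:
    """Closed-form resident equilibrium for vanishing resource decay.

    Setting both chemostat equations to zero with mu_j = 0 forces every
    resource's supply to be consumed, giving n* = sum_j s_j / delta and
    r_j* = s_j / (n* alpha_j**q_j).  Feasibility demands r_j* < 1 (the Monod
    response cannot reach 1 at finite concentration); otherwise an
    :class:`InfeasibleEquilibriumError` is raised.
    """
    if np.any(env.decay != 0):
        raise ValueError("closed-form equilibrium requires mu = 0")
    if env.death_rate <= 0:
        raise ValueError("closed-form equilibrium requires delta > 0")
    a_eff = phenotype.alpha**env.uptake_exponent
    s = env.supply
    if np.any((s > 0) & (a_eff == 0)):
        raise InfeasibleEquilibriumError(
            "resident allocates nothing to a supplied resource"
        )
    n_star = float(np.sum(s)) / env.death_rate
    r = np.where(s > 0, s / (n_star * np.where(a_eff > 0, a_eff, 1.0)), 0.0)
    if np.any(r >= 1.0):
        raise InfeasibleEquilibriumError(
            f"demand cannot balance supply: max r* = {r.max():.6g} >= 1"
        )
    c = env.monod_K * r / (1.0 - r)
    return Mu0Equilibrium(density=n_star, uptake=r, concentration=c)
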