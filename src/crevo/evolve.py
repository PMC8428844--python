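"""Mutation-selection dynamics of a polymorphic strain population.

The engine alternates ecological relaxation (chemostat integration or a few
serial-dilution batches) with rare mutation events, the timescale separation
assumed by adaptive dynamics.  Each epoch, parents are drawn with
probability proportional to density and each spawns a mutant strain: an
isotropic Gaussian step of scale sigma in allocation space, clipped at the
non-negativity boundary and radially retracted onto the tradeoff surface
(so exact specialist vertices are reachable).  Strains falling below the
extinction threshold are culled by the ecology step.

The long-run outcome depends on the curvature of the tradeoff: a concave
budget (gamma < 1) drives convergence to the singular generalist followed by
evolutionary branching into (at most) one specialist per resource; a convex
budget (gamma > 1) halts evolution at the generalist; the linear budget is
selectively neutral at the singular point and the population broadens
diffusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .chemostat import IntegrationControl, integrate
from .core import (
    CommunityState,
    EnvironmentSpec,
    Phenotype,
    TradeoffSpec,
    project_to_constraint,
)
from .dilution import DilutionProtocol, dilute, run_batch
from .observe import cluster_phenotypes

__all__ = [
    "EvolutionParams",
    "EvolutionTrajectory",
    "SerialEcology",
    "mutate",
    "run_evolution",
    "monomorphic_convergence_test",
]


@dataclass(frozen=True)
class SerialEcology:
    """Serial-dilution ecology bundle: the protocol plus the environment
    carrying the Monod constants and uptake exponents."""

    protocol: DilutionProtocol
    env: EnvironmentSpec


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the mutation-selection loop.

    The defaults separate ecological and evolutionary timescales: one
    mutant per epoch, each epoch long enough for the ecology to sort
    out invaders (100 chemostat time units / 5 dilution batches), mutants
    seeded at a small fraction of the parent density.
    """

    mutation_sigma: float = 0.02
    mutations_per_epoch: int = 3
    epoch_duration: float = 100.0
    epoch_batches: int = 2
    mutant_fraction: float = 0.02
    max_epochs: int = 4000
    rng_seed: int = 0
    stop_window: int = 300
    stop_mean_tol: float = 0.005
    stop_var_rel_tol: float = 0.25
    stop_var_abs_tol: float = 5e-4
    cluster_cutoff: float = 0.2
    merge_distance: float | None = None  # None -> 0.5 * mutation_sigma

    def __post_init__(self):
        if not 0 < self.mutation_sigma <= 0.2:
            raise ValueError("mutation_sigma must lie in (0, 0.2]")
        if not 0 < self.mutant_fraction <= 0.1:
            raise ValueError("mutant_fraction must lie in (0, 0.1]")
        if self.mutations_per_epoch < 1 or self.max_epochs < 1:
            raise ValueError("counts must be positive integers")

    @property
    def merge_dist(self) -> float:
        return (
            0.5 * self.mutation_sigma
            if self.merge_distance is None
            else self.merge_distance
        )


@dataclass
class EvolutionTrajectory:
    """Per-epoch snapshots of the evolving community plus the event log."""

    snapshots: list[CommunityState] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def final_state(self) -> CommunityState:
        return self.snapshots[-1]

    def mean_trajectory(self) -> np.ndarray:
        """(epochs, p) density-weighted mean allocation over time."""
        return np.array([s.mean_phenotype() for s in self.snapshots])


def mutate(
    parent: Phenotype,
    sigma: float,
    rng: np.random.Generator,
    spec: TradeoffSpec,
    max_retries: int = 100,
) -> Phenotype:
    """One mutational step: Gaussian perturbation, clip, retract.

    The isotropic step is clipped at zero componentwise and radially
    projected back onto the budget surface; the all-zero degenerate draw is
    resampled (bounded retries).
    """
    for _ in range(max_retries):
        raw = np.maximum(parent.alpha + sigma * rng.standard_normal(parent.p), 0.0)
        if np.any(raw > 0):
            return project_to_constraint(raw, spec)
    raise RuntimeError("mutation resampling failed to leave the origin")


def _merge_strains(state: CommunityState, distance: float) -> None:
    """Coarse-grain the strain list in place: strains closer than
    ``distance`` (Euclidean, allocation space) to an already-kept denser
    strain donate their density to it.

    Keeps the strain list bounded near selective neutrality, where
    near-identical lineages would otherwise accumulate without limit; the
    merge radius sits well below the mutation step, so cloud broadening and
    branching are unaffected.
    """
    if distance <= 0 or state.n_strains < 2:
        return
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(state.alpha_matrix()))
    order = np.argsort(-state.densities())
    kept_idx: list[int] = []
    extra = np.zeros(state.n_strains)
    for i in order:
        close = [k for k in kept_idx if D[i, k] < distance]
        if close:
            extra[close[0]] += state.strains[i][1]
        else:
            kept_idx.append(i)
    if len(kept_idx) < state.n_strains:
        keep = sorted(kept_idx)
        state.strains = [
            (state.strains[i][0], state.strains[i][1] + extra[i]) for i in keep
        ]


def _trait_variance(state: CommunityState) -> float:
    """Density-weighted mean squared distance from the mean allocation."""
    n = state.densities()
    A = state.alpha_matrix()
    mean = (A * n[:, None]).sum(axis=0) / n.sum()
    return float((n * ((A - mean) ** 2).sum(axis=1)).sum() / n.sum())


def _within_cluster_variance(state: CommunityState, labels: np.ndarray) -> float:
    """Largest density-weighted trait variance within any single cluster;
    grows while a cluster cloud is broadening toward its own branching."""
    n = state.densities()
    A = state.alpha_matrix()
    worst = 0.0
    for lab in np.unique(labels):
        m = labels == lab
        w = n[m]
        tot = w.sum()
        if tot <= 0:
            continue
        mean = (A[m] * w[:, None]).sum(axis=0) / tot
        worst = max(worst, float((w * ((A[m] - mean) ** 2).sum(axis=1)).sum() / tot))
    return worst


def _ecology_epoch(
    state: CommunityState,
    ecology: Union[EnvironmentSpec, SerialEcology],
    evo: EvolutionParams,
    ctrl: IntegrationControl,
) -> CommunityState:
    if isinstance(ecology, EnvironmentSpec):
        return integrate(state, ecology, ctrl, evo.epoch_duration)
    cutoff = 1e-9 * ecology.protocol.rho0
    cur = state
    for _ in range(evo.epoch_batches):
        final, _ = run_batch(cur, ecology.protocol, ecology.env, ctrl)
        cur = dilute(final, ecology.protocol)
        cur.strains = [(ph, n) for ph, n in cur.strains if n >= cutoff]
    return cur


def run_evolution(
    initial: Union[Phenotype, CommunityState],
    ecology: Union[EnvironmentSpec, SerialEcology],
    evo: EvolutionParams,
    ctrl: IntegrationControl,
    spec: TradeoffSpec,
) -> EvolutionTrajectory:
    """Long-run mutation-selection simulation.

    ``initial`` is either a single ancestral phenotype (a monomorphic start
    at the ecology's characteristic density) or a full ``CommunityState``
    (e.g. an already-assembled specialist coalition).  Runs up to
    ``evo.max_epochs`` epochs, stopping early once the density-weighted
    mean strategy, the phenotypic cluster count and the trait variances
    have been stationary for ``evo.stop_window`` consecutive epochs.
    """
    rng = np.random.default_rng(evo.rng_seed)
    if isinstance(initial, CommunityState):
        state = initial.copy()
    elif isinstance(ecology, EnvironmentSpec):
        n0 = float(np.sum(ecology.supply)) / max(ecology.death_rate, 1e-3)
        state = CommunityState(
            strains=[(initial, n0)],
            concentrations=ecology.monod_K.copy(),
            time=0.0,
        )
    else:
        state = CommunityState(
            strains=[(initial, ecology.protocol.rho0)],
            concentrations=ecology.protocol.c_init.copy(),
            time=0.0,
        )

    traj = EvolutionTrajectory()
    means: list[np.ndarray] = []
    counts: list[int] = []
    variances: list[float] = []
    within: list[float] = []
    for epoch in range(evo.max_epochs):
        state = _ecology_epoch(state, ecology, evo, ctrl)
        if not state.strains:
            traj.events.append({"epoch": epoch, "type": "collapse"})
            break
        _merge_strains(state, evo.merge_dist)
        traj.snapshots.append(state.copy())
        means.append(state.mean_phenotype())
        summary = cluster_phenotypes(state, evo.cluster_cutoff)
        counts.append(summary.n_clusters)
        variances.append(_trait_variance(state))
        within.append(_within_cluster_variance(state, summary.labels))

        # stationarity over the window of: mean strategy, cluster count,
        # total trait variance (inter-cluster divergence still in progress
        # shows up here) and the largest within-cluster variance (a cloud
        # broadening toward its own branching shows up here, while mean and
        # count are already stationary)
        w = evo.stop_window
        if epoch + 1 >= w:
            recent = np.array(means[-w:])
            drift = np.linalg.norm(recent - recent[-1], axis=1).max()

            def _stable(series):
                v = np.array(series[-w:])
                return np.abs(v - v[-1]).max() <= max(
                    evo.stop_var_rel_tol * v[-1], evo.stop_var_abs_tol
                )

            if (
                drift < evo.stop_mean_tol
                and len(set(counts[-w:])) == 1
                and _stable(variances)
                and _stable(within)
            ):
                traj.stopped_early = True
                break

        densities = state.densities()
        probs = densities / densities.sum()
        parent_ids = rng.choice(
            len(state.strains), size=evo.mutations_per_epoch, p=probs
        )
        for idx in parent_ids:
            idx = int(idx)
            parent, n_parent = state.strains[idx]
            child = mutate(parent, evo.mutation_sigma, rng, spec)
            dn = evo.mutant_fraction * n_parent
            state.strains[idx] = (parent, n_parent - dn)
            state.strains.append((child, dn))
            traj.events.append(
                {
                    "epoch": epoch,
                    "type": "mutation",
                    "parent": parent.alpha.tolist(),
                    "child": child.alpha.tolist(),
                    "seed_density": dn,
                }
            )
    return traj


def monomorphic_convergence_test(
    initial: Phenotype,
    ecology: Union[EnvironmentSpec, SerialEcology],
    evo: EvolutionParams,
    ctrl: IntegrationControl,
    spec: TradeoffSpec,
    alpha_star: Phenotype,
) -> np.ndarray:
    """Distance of the population mean from the singular strategy over time.

    Runs :func:`run_evolution` and returns the per-epoch Euclidean distance
    of the density-weighted mean allocation from ``alpha_star``; under the
    adaptive-dynamics prediction this decays below the cluster scale before
    any branching begins, for every tradeoff exponent.
    """
    traj = run_evolution(initial, ecology, evo, ctrl, spec)
    means = traj.mean_trajectory()
    return np.linalg.norm(means - alpha_star.alpha, axis=1)
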