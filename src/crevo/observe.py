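"""Post-processing observables: clustering strain clouds into species,
specialist/generalist calls, simplex projection, and the pure-ecology
community-assembly experiment.

Under mutation-selection balance each species is a tight cloud of strains;
single-linkage clustering at a fixed cutoff (well above cloud width, well
below the inter-vertex distance) turns clouds into species counts.  The
simplex projection maps a strategy to its budget shares
(alpha_j**gamma_j / E), which sum to one -- the natural coordinates for
visualizing p = 3 communities and for calling specialists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .chemostat import IntegrationControl, integrate_to_stationarity
from .core import (
    CommunityState,
    EnvironmentSpec,
    Phenotype,
    TradeoffSpec,
    _vector,
)
from .dilution import DilutionProtocol, dilute, run_batch

__all__ = [
    "Cluster",
    "ClusterSummary",
    "cluster_phenotypes",
    "classify_specialist",
    "simplex_coordinates",
    "ecological_assembly",
    "sample_random_phenotypes",
]


@dataclass(frozen=True)
class Cluster:
    center: np.ndarray          # density-weighted mean allocation
    total_density: float
    n_strains: int
    is_specialist: bool | None = None
    specialist_resource: int | None = None


@dataclass(frozen=True)
class ClusterSummary:
    clusters: list[Cluster]
    linkage_cutoff: float
    labels: np.ndarray          # per-strain cluster index

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def total_density(self) -> float:
        return float(sum(c.total_density for c in self.clusters))


def cluster_phenotypes(
    community: CommunityState,
    cutoff: float = 0.2,
    spec: TradeoffSpec | None = None,
    specialist_threshold: float = 0.9,
) -> ClusterSummary:
    """Single-linkage clustering of strains in allocation space.

    The dendrogram is cut at Euclidean distance ``cutoff`` (default 0.2:
    comfortably above mutation-selection cloud widths, comfortably below the
    inter-vertex distance sqrt(2)).  If ``spec`` is given, each cluster
    center is also classified as specialist or generalist.
    """
    if not community.strains:
        raise ValueError("cannot cluster an empty community")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = community.alpha_matrix()
    n = community.densities()
    if len(community.strains) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(
            linkage(pdist(A), method="single"), t=cutoff, criterion="distance"
        )
    clusters = []
    for lab in np.unique(labels):
        m = labels == lab
        w = n[m]
        total = float(w.sum())
        center = (
            (A[m] * w[:, None]).sum(axis=0) / total
            if total > 0
            else A[m].mean(axis=0)
        )
        is_spec = res = None
        if spec is not None:
            is_spec, res = classify_specialist(
                center, spec, threshold=specialist_threshold
            )
        clusters.append(
            Cluster(
                center=center,
                total_density=total,
                n_strains=int(m.sum()),
                is_specialist=is_spec,
                specialist_resource=res,
            )
        )
    clusters.sort(key=lambda c: -c.total_density)
    return ClusterSummary(clusters=clusters, linkage_cutoff=cutoff, labels=labels)


def classify_specialist(
    center, spec: TradeoffSpec, threshold: float = 0.9
) -> tuple[bool, int | None]:
    """Specialist iff one resource absorbs >= ``threshold`` of the budget.

    Budget shares are alpha_j**gamma_j / E; returns (flag, argmax resource
    index or None for a generalist).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    shares = simplex_coordinates(center, spec)
    j = int(np.argmax(shares))
    if shares[j] >= threshold:
        return True, j
    return False, None


def simplex_coordinates(phenotype, spec: TradeoffSpec) -> np.ndarray:
    """Budget shares (alpha_j**gamma_j / E), a point on the unit simplex."""
    a = phenotype.alpha if isinstance(phenotype, Phenotype) else _vector(
        phenotype, "alpha"
    )
    g = spec.gammas(a.size)
    return a**g / spec.budget


def sample_random_phenotypes(
    n_species: int,
    spec: TradeoffSpec,
    p: int,
    rng: np.random.Generator,
) -> list[Phenotype]:
    """Uniform random strategies: Dirichlet(1,..,1) budget shares mapped back
    through the componentwise power 1/gamma_j."""
    g = spec.gammas(p)
    shares = rng.dirichlet(np.ones(p), size=n_species)
    return [Phenotype((spec.budget * x) ** (1.0 / g)) for x in shares]


def ecological_assembly(
    n_species: int,
    ecology,
    spec: TradeoffSpec,
    rng: np.random.Generator,
    ctrl: IntegrationControl,
    cutoff: float = 0.2,
    max_batches: int = 2000,
    stationarity_residual: float = 1e-8,
) -> tuple[ClusterSummary, int]:
    """Community assembly with mutation switched off.

    Seeds the ecology with ``n_species`` strategies drawn uniformly on the
    budget-share simplex and runs pure population dynamics -- to
    stationarity for a chemostat ``EnvironmentSpec``, or to a periodic
    steady state (relative end-of-batch change < 1e-6) for a
    ``(DilutionProtocol, EnvironmentSpec)`` pair.  Returns the surviving
    cluster summary and the number of surviving species (strains): under a
    linear tradeoff the many coexisting survivors spread over the simplex
    and chain into few clusters, so the strain count is the faithful
    diversity measure.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")

    if isinstance(ecology, EnvironmentSpec):
        env = ecology
        phenos = sample_random_phenotypes(n_species, spec, env.p, rng)
        n0 = float(np.sum(env.supply)) / max(env.death_rate, 1e-3) / n_species
        state = CommunityState(
            strains=[(ph, n0) for ph in phenos],
            concentrations=env.monod_K.copy(),
        )
        final = integrate_to_stationarity(
            state, env, ctrl, residual=stationarity_residual
        )
    else:
        protocol, env = ecology
        phenos = sample_random_phenotypes(n_species, spec, env.p, rng)
        n0 = protocol.rho0 / n_species
        state = CommunityState(
            strains=[(ph, n0) for ph in phenos],
            concentrations=protocol.c_init.copy(),
        )
        final = _dilution_steady_state(state, protocol, env, ctrl, max_batches)

    summary = cluster_phenotypes(final, cutoff=cutoff, spec=spec)
    return summary, final.n_strains


def _dilution_steady_state(
    state: CommunityState,
    protocol: DilutionProtocol,
    env: EnvironmentSpec,
    ctrl: IntegrationControl,
    max_batches: int,
    rel_change: float = 1e-6,
) -> CommunityState:
    cutoff = 1e-9 * protocol.rho0
    prev = None
    cur = state
    final = cur
    for _ in range(max_batches):
        final, _ = run_batch(cur, protocol, env, ctrl)
        vec = {id(ph): n for ph, n in final.strains}
        if prev is not None and prev.keys() == vec.keys():
            num = max(
                abs(vec[k] - prev[k]) / max(prev[k], 1e-300) for k in vec
            )
            if num < rel_change:
                break
        prev = vec
        cur = dilute(final, protocol)
        cur.strains = [(ph, n) for ph, n in cur.strains if n >= cutoff]
    return final
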