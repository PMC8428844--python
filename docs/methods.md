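# Methods

## Model

A community is a finite set of strains, each defined by an allocation
strategy `α` on the budget surface `Σ_j α_j^{γ_j} = E` with `γ_j, E > 0`.
Uptake of resource *j* contributes `α_j^{q_j} r_j(c_j)` to the per-capita
birth rate, with Monod response `r_j(c) = c/(K_j + c)`; the optional uptake
exponents `q_j` (default 1) let the same non-linearity live in the rates
instead of the budget.  The chemostat adds constant supply `s_j`, abiotic
decay `μ_j` and a uniform death rate `δ`; the serial-dilution protocol
replaces them with batch growth from inoculum `ρ₀` in fresh medium
`c_j(0)`, stopped at `Σ_j c_j = c_fin` and followed by dilution.  Both
ecologies share one right-hand side (`α_j^{q_j}` applied identically in
growth and consumption, so biomass bookkeeping is consistent); the batch is
the chemostat with `s = μ = δ = 0` plus a terminal depletion event.

Assumptions worth keeping in mind: resources are substitutable, the
environment is well mixed, strategies are fixed per strain (no phenotypic
plasticity, no regulation), and mutation is rare relative to ecological
sorting.

## Default parameterization

| parameter | default | meaning / rationale |
|---|---|---|
| `p` | 3 | number of resources (all presets) |
| `E` | 1 | budget scale; strategies are dimensionless shares |
| `s_j` | 1 | symmetric supply |
| `K_j`, `μ_j` | 1, 0.1 | only the product μK = 0.1 matters for the feasible range of r (c ≤ s/μ gives r ≤ (s/μ)/(K+s/μ)); K = 1 makes c and K share units |
| `δ` | 0.25 | chemostat death rate; n* = Σs/δ = 12 |
| `ρ₀`, `c_fin` | 10⁻³, 10⁻⁸ | dilution inoculum and depletion threshold |
| `c_j(0)` | K (also 10K, 0.1K) | fresh-medium regimes |

Note the linear-tradeoff chemostat at δ = 1 admits no growing consumer
under these parameters: `r ≤ (s/μ)/(K + s/μ) = 10/11 < δ` everywhere, and
the μ=0 equilibrium sits exactly on the infeasibility boundary `r* = 1`
(`resident_equilibrium_mu0` raises).  Neutral linear-tradeoff behaviour is
therefore demonstrated at δ = 0.25 (chemostat) and in serial dilution,
where no death rate enters.

## Adaptive dynamics

For `μ = 0` the monomorphic resident equilibrium is closed form
(`n* = Σ_j s_j/δ`, `r_j* = s_j/(n* α_j^{q_j})`, feasible iff all
`r_j* < 1`), which makes invasion fitness closed form:
`f(α′; α) = Σ_j α′_j^{q_j} r_j* − δ`.  For `μ > 0` the resident is
equilibrated by integration and `f` evaluated at its stationary
concentrations (flagged approximate; the analytics hold at μ = 0).

All derivative quantities are finite differences of `f` in an orthonormal
basis of the constraint tangent space (Householder completion of the unit
normal `γ_j α_j^{γ_j−1}`, deterministic ordering).  Off-surface points are
retracted radially (`project_to_constraint`, exact for uniform γ, bracketed
root otherwise, residual ≤ 1e−12).  Steps: gradient 1e−6 (central),
Hessian and Jacobian 1e−3 (central second differences).  The Hessian step
is the one genuinely delicate choice: the classification tolerance for
neutrality is `1e−8·δ`, and a step of 1e−4 leaves a rounding floor
`ε/h² ≈ 1e−8` in the second difference that would swamp it; at 1e−3 the
floor is ~1e−10 while the truncation error is still ~1e−6 of the eigenvalue
scale.  Sign stability under halving/doubling the step is part of the test
suite.

Because `f` is linear in the mutant, the tangent Hessian is pure constraint
curvature (`−λ · U^T diag(γ_j(γ_j−1)α_j^{γ_j−2}) U` with λ > 0), which is
why its eigenvalues carry the sign of `1 − γ_j`: concave budgets make the
singular point a branching point, convex ones an ESS, and the linear case
is exactly neutral.  For per-direction exponents the singular point is the
tangency condition `α_j^{γ_j} = E (s_j/γ_j) / Σ_k (s_k/γ_k)` — the naive
componentwise power of the uniform-γ formula does not null the gradient
unless γ is uniform — and the per-direction branching flags are the signs
of the directional curvature along each resource axis projected onto the
tangent space.

## Numerical integration

Chemostat chunks use the LSODA core through `scipy.integrate.odeint`
(`rtol = 1e−8`, `atol = 1e−10` defaults); batches use the explicit DOP853
`solve_ivp` solver, whose event handling locates depletion — both dynamics
have O(1) timescales throughout, so no stiff machinery is needed, and these
two interfaces (unlike `solve_ivp`'s LSODA wrapper) do not accumulate
memory over the tens of thousands of short integrations an evolution run
performs.  The Monod response is evaluated on `max(c, 0)` mid-step and stray
negatives (O(atol)) are clipped at checkpoint boundaries, where strains
below the extinction threshold (default `1e−6 · Σs/δ` via
`IntegrationControl.for_environment`) are removed.  Stationarity means
`max(|dn/dt|/n, |dc/dt|) < 1e−8`.

Batch termination uses terminal event detection on `Σc − c_fin`.  The
dense-output interpolant leaves an O(atol) residual in the event state —
far above the 1e−6-relative stopping contract at `c_fin = 1e−8` — so the
event state is Newton-polished along the vector field (a pure time shift,
hence exactly conservation-preserving) and stray negative concentrations
are clipped with the remainder rescaled to keep `Σc = c_fin` exactly.  With
`q = 1` every batch conserves `Σn + Σc` to machine precision, which the
tests assert at every solver step.

## Evolution engine

Epochs alternate ecological relaxation (100 chemostat time units, or 2
batches) with mutation events: 3 parents per epoch drawn with probability
proportional to density, each spawning a mutant at Gaussian step σ = 0.02
(clipped at the non-negativity boundary, retracted onto the surface — so
exact specialist vertices are reachable) carrying 2% of the parent's
density.  These rates compress the evolutionary timescale so that a full
branching sequence (convergence → first split → cluster migration → second
split → specialist coalition) completes in ~2000 epochs; the qualitative
outcomes are insensitive to σ and the mutation rate, which set only the
clock and the cloud width.

Two implementation details matter near selective neutrality:

* **strain coarse-graining** — strains closer than 0.5σ donate their
  density to the nearest denser strain each epoch; without it the strain
  list grows without bound where selection is weak (the merge radius is
  well below the mutation step, so cloud broadening and branching are
  unaffected);
* **stop rule** — the run ends early only when the density-weighted mean,
  the single-linkage cluster count (cutoff 0.2), the total trait variance
  *and* the largest within-cluster variance have all been stationary for
  300 consecutive epochs.  The two variance terms are essential: between
  the first and second branching the mean and count are already stationary
  while a sub-cluster is still broadening toward its own split, and during
  cluster migration only the total variance moves.

## Observables and assembly

Species are single-linkage clusters in allocation space cut at 0.2 —
above mutation–selection cloud widths (~0.05 at σ = 0.02), below the
inter-vertex distance √2.  A cluster is a specialist when one resource
holds ≥ 90% of its budget share `α_j^{γ_j}/E`.  The simplex projection
(budget shares) is the natural coordinate system for p = 3 communities.

Mutation-free assembly seeds 200 strategies drawn uniformly on the
budget-share simplex (Dirichlet(1,…,1) shares mapped through the power
1/γ_j — unbiased across resources) and runs pure ecology to stationarity
(chemostat) or a periodic steady state (relative end-of-batch change
< 1e−6).  The survivor *count* is the number of surviving strains: under a
linear budget the many coexisting survivors spread across the simplex and
chain into a single linkage cluster, so cluster count is not a diversity
measure there.  With a concave budget the three survivors are the most
vertex-like strategies present in the finite random sample; their maximal
budget shares are typically ~0.8–0.95, so assembly tests call them
specialists by distinct dominant resource (share ≥ 0.5, far from the
generalist's 1/3) rather than by the strict 0.9 threshold that evolved
(mutation-refined) specialists reach.

## What the synthetic scenarios do and do not show

All inputs are generated by the model itself; there is no external data.
The simulations demonstrate the mapping from tradeoff curvature to
diversification outcome under the stated idealizations — fixed strategies,
substitutable resources, deterministic ecology between rare mutational
events.  They do not capture demographic stochasticity (a neutral mutant's
frequency is frozen, not drifting, so γ = 1 "diffusive" broadening here is
mutation-accumulation-limited), plasticity, cross-feeding, or
non-equilibrium coexistence mechanisms.

## Problem sizes used in the checks

The acceptance suite runs the full pipeline at p = 3: five seeds per
branching scenario (chemostat, and each of the three dilution regimes),
single seeds for the convex and heterogeneous-exponent outcomes, 200
species per assembly run, and a γ sweep of 8 values for the stability sign
law.  `scripts/acceptance.py` reruns one seed per scenario.

## Known limitations

* Stability classification for μ > 0 relies on numerical equilibration and
  is approximate; the closed-form analytics require μ = 0.
* `selection_gradient` requires a strictly interior resident (the
  constraint normal diverges on the boundary for γ < 1).
* The deterministic ecology freezes neutral frequencies; genuinely neutral
  regimes (γ = 1) are explored only through mutation accumulation.
* Runtime grows with strain count; the coarse-graining radius trades
  resolution of the strain cloud against speed.
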