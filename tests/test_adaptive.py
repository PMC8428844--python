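"""Adaptive dynamics: singular strategies, invasion fitness, selection
gradients, and the curvature-driven stability classification."""

import numpy as np
import pytest

import crevo
from crevo.adaptive import BoundaryResidentError

DELTA = 0.25


def closed_form_fitness(mutant, resident, env):
    """Independent mu=0 oracle: f = delta * (sum_j (a'_j/a_j) s_j/sum(s) - 1)."""
    s = env.supply
    return env.death_rate * (
        float(np.sum(mutant.alpha / resident.alpha * s / s.sum())) - 1.0
    )


class TestSingularPoint:
    @pytest.mark.parametrize(
        "supply,gamma,expected",
        [
            ([1, 1, 1], 1.0, [1 / 3, 1 / 3, 1 / 3]),
            ([1, 1, 1], 0.5, [1 / 9, 1 / 9, 1 / 9]),
            ([2, 1, 1], 1.0, [0.5, 0.25, 0.25]),
        ],
    )
    def test_supply_share_rule(self, supply, gamma, expected):
        ph = crevo.singular_point(supply, crevo.TradeoffSpec(gamma=gamma))
        np.testing.assert_allclose(ph.alpha, expected, atol=1e-14)

    def test_on_constraint_surface(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = rng.uniform(0.1, 3, 3)
            spec = crevo.TradeoffSpec(gamma=float(rng.uniform(0.4, 2.5)))
            ph = crevo.singular_point(s, spec)
            assert abs(crevo.tradeoff_value(ph.alpha, spec) - 1.0) < 1e-12

    def test_all_zero_supply_rejected(self, spec1):
        with pytest.raises(ValueError):
            crevo.singular_point([0, 0, 0], spec1)


class TestInvasionFitness:
    def test_resident_is_neutral_against_itself(self, mu0_env, spec09):
        ph = crevo.singular_point(mu0_env.supply, spec09)
        assert crevo.invasion_fitness(ph, ph, mu0_env) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_vertex_mutant_neutral_under_linear_tradeoff(self, mu0_env):
        resident = crevo.Phenotype([1 / 3, 1 / 3, 1 / 3])
        mutant = crevo.Phenotype([1.0, 0.0, 0.0])
        assert crevo.invasion_fitness(mutant, resident, mu0_env) == (
            pytest.approx(0.0, abs=1e-14)
        )

    def test_vertex_mutant_invades_concave_generalist(self, mu0_env, spec09):
        """At gamma=0.9 the singular generalist is invadable by a
        specialist: f = delta (3**(1/0.9)/3 - 1) ~ 0.130 delta > 0."""
        resident = crevo.singular_point(mu0_env.supply, spec09)
        mutant = crevo.Phenotype([1.0, 0.0, 0.0])
        f = crevo.invasion_fitness(mutant, resident, mu0_env)
        expected = DELTA * (3 ** (1 / 0.9) / 3 - 1)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f > 0

    def test_matches_closed_form_oracle(self, mu0_env, spec09):
        rng = np.random.default_rng(5)
        for _ in range(20):
            # residents bounded away from the boundary so every resource
            # demand stays feasible (r_j* < 1 needs alpha_j > 1/12 here)
            resident = crevo.project_to_constraint(
                rng.uniform(0.4, 1, 3), spec09
            )
            mutant = crevo.project_to_constraint(rng.uniform(0.05, 1, 3), spec09)
            assert crevo.invasion_fitness(mutant, resident, mu0_env) == (
                pytest.approx(
                    closed_form_fitness(mutant, resident, mu0_env), abs=1e-10
                )
            )

    def test_numerical_mu_proxy_agrees(self, spec09, ctrl):
        """The mu>0 numerical route converges to the mu=0 closed form as
        mu -> 0."""
        env0 = crevo.EnvironmentSpec.symmetric(decay=0.0)
        env_eps = crevo.EnvironmentSpec.symmetric(decay=1e-6)
        resident = crevo.singular_point(env0.supply, spec09)
        mutant = crevo.Phenotype([1.0, 0.0, 0.0])
        f0 = crevo.invasion_fitness(mutant, resident, env0)
        f_eps = crevo.invasion_fitness(mutant, resident, env_eps, ctrl=ctrl)
        assert f_eps == pytest.approx(f0, rel=1e-3)


class TestSelectionGradient:
    def test_vanishes_at_singular_point(self, mu0_env):
        for gamma in (0.7, 1.0, 1.3):
            spec = crevo.TradeoffSpec(gamma=gamma)
            astar = crevo.singular_point(mu0_env.supply, spec)
            g = crevo.selection_gradient(astar, mu0_env, spec)
            assert np.linalg.norm(g) <= 1e-6

    def test_points_toward_singular_point_p2(self):
        env = crevo.EnvironmentSpec(
            supply=[1.0, 1.0], monod_K=[1, 1], decay=[0, 0], death_rate=DELTA
        )
        spec = crevo.TradeoffSpec(gamma=1.0)
        resident = crevo.Phenotype([0.6, 0.4])
        U = crevo.tangent_basis(resident.alpha, spec)
        g = crevo.selection_gradient(resident, env, spec)
        step = (U @ g) * 1e-3
        moved = resident.alpha + step
        assert abs(moved[0] - 0.5) < abs(resident.alpha[0] - 0.5)

    def test_permutation_equivariance(self, mu0_env, spec09):
        perm = np.array([1, 2, 0])
        resident = crevo.project_to_constraint([0.5, 0.3, 0.2], spec09)
        resident_p = crevo.Phenotype(resident.alpha[perm])
        g = crevo.selection_gradient(resident, mu0_env, spec09)
        g_p = crevo.selection_gradient(resident_p, mu0_env, spec09)
        # tangent bases differ, compare basis-independent magnitude
        assert np.linalg.norm(g) == pytest.approx(
            np.linalg.norm(g_p), rel=1e-6
        )

    def test_boundary_resident_rejected(self, mu0_env, spec09):
        with pytest.raises(BoundaryResidentError):
            crevo.selection_gradient(
                crevo.Phenotype([1.0, 0.0, 0.0]), mu0_env, spec09
            )


class TestClassification:
    def test_concave_is_branching_point(self, mu0_env, spec09):
        rep = crevo.classify_singular_point(mu0_env, spec09)
        assert rep.classification == "branching_point"
        assert rep.hessian_eigs.max() > 0
        assert np.all(np.real(rep.jacobian_eigs) < 0)

    def test_convex_is_ess_endpoint(self, mu0_env):
        rep = crevo.classify_singular_point(
            mu0_env, crevo.TradeoffSpec(gamma=1.1)
        )
        assert rep.classification == "ess_endpoint"
        assert np.all(rep.hessian_eigs < 0)
        assert np.all(np.real(rep.jacobian_eigs) < 0)

    def test_linear_is_neutral(self, mu0_env, spec1):
        rep = crevo.classify_singular_point(mu0_env, spec1)
        assert rep.classification == "neutral"
        assert np.abs(rep.hessian_eigs).max() <= 1e-8 * DELTA

    @pytest.mark.parametrize("gamma", [0.5, 0.8, 0.9, 0.99, 1.01, 1.1, 1.5, 2])
    def test_sign_law(self, mu0_env, gamma):
        """sign(max Hessian eigenvalue) = sign(1 - gamma); convergent
        stable throughout."""
        rep = crevo.classify_singular_point(
            mu0_env, crevo.TradeoffSpec(gamma=gamma)
        )
        assert np.sign(rep.hessian_eigs.max()) == np.sign(1 - gamma)
        assert np.all(np.real(rep.jacobian_eigs) < 0)

    def test_sign_law_asymmetric_supply(self):
        env = crevo.EnvironmentSpec(
            supply=[2.0, 1.0, 0.5], monod_K=1, decay=0, death_rate=DELTA
        )
        for gamma in (0.8, 1.25):
            rep = crevo.classify_singular_point(
                env, crevo.TradeoffSpec(gamma=gamma)
            )
            assert np.sign(rep.hessian_eigs.max()) == np.sign(1 - gamma)

    def test_sign_stable_under_step_halving_and_doubling(self, mu0_env):
        for gamma in (0.9, 1.1):
            spec = crevo.TradeoffSpec(gamma=gamma)
            signs = {
                np.sign(
                    crevo.classify_singular_point(
                        mu0_env, spec, hessian_step=h
                    ).hessian_eigs.max()
                )
                for h in (5e-4, 1e-3, 2e-3)
            }
            assert len(signs) == 1

    def test_heterogeneous_exponents_flag_concave_directions(self, mu0_env):
        """gamma = (0.9, 1.1, 1.1): branching along direction 1 only."""
        spec = crevo.TradeoffSpec(gamma=[0.9, 1.1, 1.1])
        rep = crevo.classify_singular_point(mu0_env, spec)
        np.testing.assert_array_equal(
            rep.per_direction, [True, False, False]
        )
        assert rep.classification == "branching_point"
        g = crevo.selection_gradient(rep.alpha_star, mu0_env, spec)
        assert np.linalg.norm(g) <= 1e-6
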