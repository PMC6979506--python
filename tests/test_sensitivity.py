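import numpy as np
import pytest

import lro
from lro.lifecycle import (
    LifeCycleModel,
    StageDecomposition,
    build_markov_chain,
    decompose_stage_model,
)
from lro.moments import lro_moment_vectors, lro_statistics
from lro.rewards import FertilitySchedule
from lro.sensitivity import (
    PerturbationMap,
    age_classified_pmap,
    compensated_growth_direction,
    compensated_growth_pmap,
    dP_from_dU,
    elasticity,
    fertility_pmap,
    moment_sensitivity,
    stage_classified_pmap,
    statistic_sensitivity,
    vec_permutation,
)

from conftest import make_models
from fd_oracle import (
    age_pmap_cases,
    analytic_stats,
    central_fd,
    max_relative_error,
    pmap_cases,
)


class TestVecPermutation:
    def test_row_vector_case_is_identity(self):
        np.testing.assert_array_equal(vec_permutation(1, 4), np.eye(4))

    def test_transpose_identity(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        K = vec_permutation(2, 2)
        np.testing.assert_array_equal(
            K @ X.flatten(order="F"), X.T.flatten(order="F")
        )

    @pytest.mark.parametrize("m,n", [(2, 3), (4, 2), (3, 3)])
    def test_involution_pair(self, m, n):
        np.testing.assert_array_equal(
            vec_permutation(m, n) @ vec_permutation(n, m), np.eye(m * n)
        )

    @pytest.mark.parametrize("m,n", [(2, 5), (3, 4)])
    def test_general_transpose_property(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        X = rng.normal(size=(m, n))
        np.testing.assert_allclose(
            vec_permutation(m, n) @ X.flatten(order="F"), X.T.flatten(order="F")
        )


class TestChainDerivative:
    def test_matches_dense_kronecker_formula(self):
        # implicit dP construction vs the dense block operator
        rng = np.random.default_rng(5)
        tau = 3
        s = tau + 1
        dU = rng.normal(size=(tau * tau, 4))
        top = np.vstack([np.eye(tau), np.zeros((1, tau))])
        bot = np.vstack([np.zeros((tau, 1)), np.eye(1)])
        C1 = np.kron(top, top)
        C2 = np.kron(top, bot)
        dense = (C1 - C2 @ np.kron(np.eye(tau), np.ones((1, tau)))) @ dU
        np.testing.assert_allclose(dP_from_dU(dU, tau), dense, atol=1e-12)

    def test_multiple_absorbing_requires_explicit_dP(self):
        pmap = PerturbationMap(
            theta=np.ones(1), dU=np.zeros((4, 1)), tau=2, alpha=2
        )
        with pytest.raises(ValueError, match="perturbation map incomplete"):
            pmap.dP_matrix()


class TestMomentSensitivity:
    def test_zero_perturbation_gives_zero_sensitivity(self, tsuga, tsuga_chain):
        rewards = tsuga.fertility.reward_moments(m=2)
        pmap = PerturbationMap(theta=np.ones(3), dU=np.zeros((36, 3)), tau=6)
        res = moment_sensitivity(tsuga_chain, rewards, pmap, m=2)
        np.testing.assert_array_equal(res.d_rho[1], 0.0)
        np.testing.assert_array_equal(res.d_rho[2], 0.0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_all_perturbation_maps_match_finite_differences(self, seed):
        model = lro.generate_synthetic_model(
            4, seed=seed, profile="stage_like", fertility_model="poisson"
        )
        for name, pmap, build, theta0 in pmap_cases(model):
            ana = analytic_stats(model, model.fertility, pmap)
            num = central_fd(build, theta0)
            err = max_relative_error(ana, num)
            assert err < 1e-5, f"{name}: max relative error {err:.2e}"

    def test_age_classified_maps_match_finite_differences(self):
        model = lro.generate_synthetic_model(5, seed=21, profile="age_like")
        for name, pmap, build, theta0 in age_pmap_cases(model):
            ana = analytic_stats(model, model.fertility, pmap)
            num = central_fd(build, theta0)
            err = max_relative_error(ana, num)
            assert err < 1e-5, f"{name}: max relative error {err:.2e}"

    def test_third_moment_sensitivity_matches_finite_differences(self):
        # order-3 recursion (3 W_{1,2} + 3 W_{2,1} terms) against FD
        model = lro.generate_synthetic_model(
            3, seed=31, profile="stage_like", fertility_model="poisson"
        )
        fert = model.fertility
        chain = build_markov_chain(model)
        rewards = fert.reward_moments(m=3)
        mv = lro_moment_vectors(chain, rewards)
        pmap = fertility_pmap(fert, mode="linked")
        res = moment_sensitivity(chain, rewards, pmap, m=3, moments=mv)

        def build(th):
            f2 = FertilitySchedule(th, model="poisson")
            mv2 = lro_moment_vectors(chain, f2.reward_moments(m=3))
            return {"rho3": mv2.raw(3)}

        num = central_fd(build, fert.f1.copy())
        err = np.max(
            np.abs(res.d_rho[3] - num["rho3"]) / np.maximum(np.abs(num["rho3"]), 1e-3)
        )
        assert err < 1e-5

    def test_order_one_ignores_higher_reward_moments(self):
        # d rho~_1 must not involve dR_2, dR_3
        model = make_models(1, taus=(3,), seed0=60)[0]
        chain = build_markov_chain(model)
        rewards = model.fertility.reward_moments(m=2)
        base = fertility_pmap(model.fertility, mode="variance_fixed_mean")
        res = moment_sensitivity(chain, rewards, base, m=2)
        np.testing.assert_array_equal(res.d_rho[1], 0.0)
        assert np.any(res.d_rho[2] != 0)

    def test_mortality_reduces_mean_lro_before_end_of_reproduction(self):
        model = lro.generate_synthetic_model(6, seed=44, profile="age_like")
        omega = model.tau
        mu = np.full(omega, 0.3)
        mu[:-1] = -np.log(np.diag(model.U, -1))
        sched = lro.AgeClassifiedSchedule(mu=mu, f=model.fertility.f1)
        chain = build_markov_chain(model)
        res = moment_sensitivity(
            chain,
            model.fertility.reward_moments(m=2),
            age_classified_pmap(sched, wrt="mu"),
            m=1,
        )
        # fertility is positive at every age here, so every age is
        # pre-end-of-reproduction except the last (which has no survival)
        assert np.all(res.d_rho[1][0, :-1] <= 0)


class TestStatisticSensitivity:
    def test_chain_rule_identity_for_crow_index(self, tsuga, tsuga_chain):
        rewards = tsuga.fertility.reward_moments(m=2)
        mv = lro_moment_vectors(tsuga_chain, rewards)
        pmap = stage_classified_pmap(decompose_stage_model(tsuga.U), wrt="mu")
        res = statistic_sensitivity(
            moment_sensitivity(tsuga_chain, rewards, pmap, m=2, moments=mv), mv
        )
        st = lro_statistics(mv)
        np.testing.assert_allclose(
            res.d_crow, 2.0 * st.cv[:, None] * res.d_cv, rtol=1e-12
        )
        np.testing.assert_allclose(
            res.d_variance,
            res.d_rho[2] - 2.0 * mv.raw(1)[:, None] * res.d_rho[1],
            rtol=1e-12,
        )

    def test_fixed_reward_variance_insensitive_on_deterministic_life(self):
        # one-step deterministic life, fixed rewards: V = 0 identically in f1,
        # so dV/df1 = 0 (mean-fixed-variance map holds v = 0 fixed)
        fert = FertilitySchedule([2.0], model="fixed")
        model = LifeCycleModel(U=[[0.0]], fertility=fert)
        chain = build_markov_chain(model)
        rewards = fert.reward_moments(m=2)
        mv = lro_moment_vectors(chain, rewards)
        pmap = fertility_pmap(fert, mode="mean_fixed_variance")
        res = statistic_sensitivity(
            moment_sensitivity(chain, rewards, pmap, m=2, moments=mv), mv
        )
        np.testing.assert_allclose(res.d_variance, 0.0, atol=1e-12)

    def test_sd_zero_reported_undefined(self):
        fert = FertilitySchedule([2.0], model="fixed")
        model = LifeCycleModel(U=[[0.0]], fertility=fert)
        chain = build_markov_chain(model)
        rewards = fert.reward_moments(m=2)
        mv = lro_moment_vectors(chain, rewards)
        res = statistic_sensitivity(
            moment_sensitivity(chain, rewards, fertility_pmap(fert, mode="mean_fixed_variance"), m=2),
            mv,
        )
        assert np.all(np.isnan(res.d_sd))


class TestElasticity:
    def test_log_derivative_of_linear_map_is_one(self):
        # xi = c * theta_j has elasticity exactly 1
        theta = np.array([2.0, 5.0])
        value = 3.0 * theta
        dvalue = np.diag([3.0, 3.0])
        e = elasticity(value, dvalue, theta)
        np.testing.assert_allclose(np.diag(e), 1.0)

    def test_zero_theta_column_is_zero(self):
        e = elasticity(np.array([1.0]), np.array([[2.0, 3.0]]), np.array([0.5, 0.0]))
        assert e[0, 1] == 0.0

    def test_nonpositive_statistic_flagged(self):
        e = elasticity(np.array([0.0]), np.array([[1.0]]), np.array([1.0]))
        assert np.isnan(e[0, 0])

    def test_mean_lro_elasticity_to_uniform_fertility_scaling_is_one(self):
        # rho~_1 is degree-1 homogeneous in the mean rewards, so the
        # fertility elasticities of the mean sum to 1 over stages
        for model in make_models(4, taus=(2, 3, 4, 5), seed0=800):
            chain = build_markov_chain(model)
            rewards = model.fertility.reward_moments(m=2)
            mv = lro_moment_vectors(chain, rewards)
            pmap = fertility_pmap(model.fertility, mode="mean_fixed_variance")
            res = moment_sensitivity(chain, rewards, pmap, m=1, moments=mv)
            e = elasticity(mv.raw(1), res.d_rho[1], pmap.theta)
            np.testing.assert_allclose(e.sum(axis=1), 1.0, rtol=1e-10)

    def test_tsuga_fertility_elasticities_positive_in_reproductive_classes(
        self, tsuga, tsuga_chain
    ):
        rewards = tsuga.fertility.reward_moments(m=2)
        mv = lro_moment_vectors(tsuga_chain, rewards)
        res = statistic_sensitivity(
            moment_sensitivity(
                tsuga_chain, rewards, fertility_pmap(tsuga.fertility, mode="linked"),
                m=2, moments=mv,
            ),
            mv,
        )
        st = lro_statistics(mv)
        e_mean = elasticity(st.mean, res.d_rho[1], tsuga.fertility.f1)
        e_var = elasticity(st.variance, res.d_variance, tsuga.fertility.f1)
        assert np.all(e_mean[0, 2:] > 0)  # reproductive classes 3..6
        assert np.all(e_var[0, 2:] > 0)


class TestCompensatedGrowth:
    def test_directions_preserve_column_sums(self):
        model = make_models(1, taus=(4,), seed0=90)[0]
        dec = decompose_stage_model(model.U)
        dG = compensated_growth_direction(dec.G)
        tau = dec.tau
        for col in range(dG.shape[1]):
            direction = dG[:, col].reshape(tau, tau, order="F")
            np.testing.assert_allclose(direction.sum(axis=0), 0.0, atol=1e-12)

    def test_two_stage_hand_computed_compensation(self):
        # perturbing g_21 loads -g_11/(1-g_21) on g_11
        G = np.array([[0.7, 0.2], [0.3, 0.8]])
        dG = compensated_growth_direction(G)
        col = dG[:, 1]  # theta = g_21 (vec index 1)
        assert col[1] == pytest.approx(1.0)
        assert col[0] == pytest.approx(-0.7 / (1 - 0.3))
        assert col[2] == col[3] == 0.0

    def test_degenerate_unit_column_strict_raises(self):
        dec = StageDecomposition(G=np.array([[1.0, 0.4], [0.0, 0.6]]), sigma=[0.9, 0.8])
        with pytest.raises(ValueError, match="degenerate compensation"):
            compensated_growth_pmap(dec, strict=True)
        # default: the degenerate direction is uncompensated, others intact
        pmap = compensated_growth_pmap(dec)
        assert pmap.dU.shape == (4, 4)

    def test_tsuga_stasis_elasticity_signs(self, tsuga, tsuga_chain):
        # negative for size classes 1-5, positive for the largest class
        dec = decompose_stage_model(tsuga.U)
        rewards = tsuga.fertility.reward_moments(m=2)
        mv = lro_moment_vectors(tsuga_chain, rewards)
        res = moment_sensitivity(
            tsuga_chain, rewards, compensated_growth_pmap(dec), m=1, moments=mv
        )
        e = elasticity(mv.raw(1), res.d_rho[1], dec.G.flatten(order="F"))
        stasis = np.array([e[0, j * 6 + j] for j in range(6)])
        assert np.all(stasis[:5] < 0) and stasis[5] > 0

    def test_tsuga_mortality_elasticities_negative_all_classes(
        self, tsuga, tsuga_chain
    ):
        dec = decompose_stage_model(tsuga.U)
        rewards = tsuga.fertility.reward_moments(m=2)
        mv = lro_moment_vectors(tsuga_chain, rewards)
        res = statistic_sensitivity(
            moment_sensitivity(
                tsuga_chain, rewards, stage_classified_pmap(dec, wrt="mu"),
                m=2, moments=mv,
            ),
            mv,
        )
        st = lro_statistics(mv)
        e_mean = elasticity(st.mean, res.d_rho[1], dec.mu)
        e_var = elasticity(st.variance, res.d_variance, dec.mu)
        assert np.all(e_mean[0] < 0) and np.all(e_var[0] < 0)


class TestFertilityPmapModes:
    def test_variance_mode_rejected_for_bernoulli(self):
        fert = FertilitySchedule([0.5], model="bernoulli")
        with pytest.raises(ValueError, match="not independent"):
            fertility_pmap(fert, mode="variance_fixed_mean")

    def test_mean_lro_insensitive_to_fertility_variance(self):
        model = make_models(1, taus=(3,), seed0=66)[0]
        chain = build_markov_chain(model)
        rewards = model.fertility.reward_moments(m=2)
        res = moment_sensitivity(
            chain, rewards, fertility_pmap(model.fertility, mode="variance_fixed_mean"), m=2
        )
        np.testing.assert_array_equal(res.d_rho[1], 0.0)
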