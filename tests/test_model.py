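"""Model primitives: kernels, preferences, growth rates, interaction
strengths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutunet import (Community, GuildState, ModelParams, competition_kernel,
                     carrying_capacity, interaction_preference,
                     interaction_strength_matrix, mutualistic_benefit,
                     percapita_growth)
from mutunet.model import build_kernels, growth_rates, percapita_jacobian


class TestCompetitionKernel:
    def test_identical_traits_give_maximal_competition(self):
        assert competition_kernel(0.0, 0.5) == 1.0

    def test_half_maximum_at_closed_form_width(self):
        sigma = 0.7
        delta = sigma * np.sqrt(2 * np.log(2))
        assert competition_kernel(delta, sigma) == pytest.approx(0.5)

    def test_wide_kernel_limit(self):
        assert competition_kernel(1.0, 1e6) == pytest.approx(1.0)

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_symmetric_in_sign(self, delta):
        assert competition_kernel(delta, 0.4) == competition_kernel(-delta, 0.4)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            competition_kernel(1.0, 0.0)


class TestCarryingCapacity:
    def test_maximum_at_optimum(self, ref_params):
        assert carrying_capacity(3.0, "animal", ref_params) == pytest.approx(400.0)
        assert carrying_capacity(2.0, "plant", ref_params) == pytest.approx(300.0)

    def test_symmetric_around_optimum(self, ref_params):
        up = carrying_capacity(3.0 + 0.7, "animal", ref_params)
        dn = carrying_capacity(3.0 - 0.7, "animal", ref_params)
        assert up == pytest.approx(dn)

    def test_gaussian_tail(self, ref_params):
        assert carrying_capacity(30.0, "animal", ref_params) < 1e-10

    def test_normalized_variant_rescales_peak(self):
        p = ModelParams(normalized_K=True, sigma_A=0.5)
        peak = carrying_capacity(p.x_Amax, "animal", p)
        assert peak == pytest.approx(400.0 / (0.5 * np.sqrt(2 * np.pi)))


class TestMutualisticBenefit:
    def test_matched_traits_give_maximal_benefit(self, ref_params):
        assert mutualistic_benefit(1.3, 1.3, ref_params) == pytest.approx(0.1)

    def test_half_maximum_at_closed_form_mismatch(self, ref_params):
        d = ref_params.sigma_m * np.sqrt(2 * np.log(2))
        assert mutualistic_benefit(0.0, d, ref_params) == pytest.approx(0.05)

    def test_specialist_limit(self, ref_params):
        assert mutualistic_benefit(0.0, 1.0, ref_params, sigma_m=1e-3) < 1e-30


class TestInteractionPreference:
    def test_single_animal_has_unit_preferences(self, ref_params):
        comm = Community(GuildState([3.0], [50.0]),
                         GuildState([1.5, 2.0, 2.5], [10.0, 20.0, 30.0]),
                         ref_params)
        w_AP, _ = interaction_preference(comm)
        assert np.allclose(w_AP, 1.0)

    def test_identical_animals_have_unit_preferences(self, ref_params):
        comm = Community(GuildState([2.5, 2.5, 2.5], [5.0, 80.0, 200.0]),
                         GuildState([1.0, 2.0], [30.0, 40.0]), ref_params)
        w_AP, _ = interaction_preference(comm)
        assert np.allclose(w_AP, 1.0)

    def test_two_animal_hand_computation(self, ref_params):
        # benefits of the two animals toward the single plant are 0.1, 0.05
        p = ref_params
        y = 2.0
        x1 = y  # b = c = 0.1
        x2 = y + p.sigma_m * np.sqrt(2 * np.log(2))  # b = 0.05
        comm = Community(GuildState([x1, x2], [1.0, 3.0]),
                         GuildState([y], [10.0]), p)
        w_AP, _ = interaction_preference(comm)
        # w = b * sum(A) / sum(A_k b_k) with sum(A)=4, denom=0.25
        assert w_AP[:, 0] == pytest.approx([1.6, 0.8])

    def test_invariant_to_partner_density_rescaling(self, ref_params):
        rng = np.random.default_rng(1)
        comm = Community(GuildState(rng.normal(3, 1, 3), rng.uniform(1, 50, 3)),
                         GuildState(rng.normal(2, 1, 4), rng.uniform(1, 50, 4)),
                         ref_params)
        w1, v1 = interaction_preference(comm)
        scaled = comm.with_densities(comm.animals.densities * 7.3,
                                     comm.plants.densities)
        w2, v2 = interaction_preference(scaled)
        assert np.allclose(w1, w2)  # animal prefs depend on animal ratios

    def test_zero_partner_column_gets_zero_preference(self, ref_params):
        comm = Community(GuildState([3.0], [0.0]),
                         GuildState([2.0], [10.0]), ref_params)
        w_AP, w_PA = interaction_preference(comm)
        assert np.all(w_AP == 0.0)  # no animal density: denominators vanish


class TestPercapitaGrowth:
    def test_logistic_equilibrium(self, single_logistic):
        f_A, f_P = percapita_growth(single_logistic)
        assert abs(f_A[0]) < 1e-12
        assert f_P.size == 0

    def test_reduces_to_logistic_competition_without_mutualism(self):
        # with c = 0 and shared traits the kernel collapses to 1
        p = ModelParams(c=0.0)
        A1, A2 = 120.0, 90.0
        comm = Community(GuildState([3.0, 3.0], [A1, A2]),
                         GuildState([2.0], [50.0]), p)
        f_A, _ = percapita_growth(comm)
        K = carrying_capacity(3.0, "animal", p)
        expect = p.r_A * (1 - (A1 + A2) / K)
        assert f_A == pytest.approx([expect, expect])

    def test_competition_limit_random_communities(self):
        # c = 0 must reproduce the plain logistic-competition growth rates
        rng = np.random.default_rng(5)
        p = ModelParams(c=0.0, sigma_C=0.5)
        for _ in range(10):
            n = rng.integers(1, 6)
            x = rng.normal(3, 1, n)
            A = rng.uniform(1, 300, n)
            comm = Community(GuildState(x, A), GuildState([], []), p)
            f_A, _ = percapita_growth(comm)
            gamma = np.exp(-(x[:, None] - x[None, :]) ** 2 / (2 * 0.5 ** 2))
            K = carrying_capacity(x, "animal", p)
            direct = p.r_A - p.r_A * (gamma @ A) / K
            assert np.allclose(f_A, direct, atol=1e-12)

    def test_empty_guild_gives_empty_vector(self, ref_params):
        comm = Community(GuildState([], []), GuildState([2.0], [10.0]),
                         ref_params)
        f_A, f_P = percapita_growth(comm)
        assert f_A.size == 0 and f_P.size == 1


class TestInteractionStrengthMatrix:
    def test_hand_computed_single_pair(self):
        # matched pair: b = c = 0.1, w = 1 on both sides, A = P = 10
        p = ModelParams()
        comm = Community(GuildState([2.0], [10.0]), GuildState([2.0], [10.0]), p)
        Q = interaction_strength_matrix(comm)
        # 0.5 * [10*0.1*1*10/(1+0.1*1*10)] * 2 = 5
        assert Q.Q[0, 0] == pytest.approx(5.0)

    def test_zero_density_gives_zero_strength(self, ref_params):
        comm = Community(GuildState([2.0, 3.0], [10.0, 0.0]),
                         GuildState([2.0], [10.0]), ref_params)
        Q = interaction_strength_matrix(comm)
        assert Q.Q[1, 0] == 0.0

    def test_threshold_rule_stores_exact_zero(self, ref_params):
        # a hopeless trait mismatch yields q below 1e-8, stored as 0
        comm = Community(GuildState([2.0, 30.0], [10.0, 1e-4]),
                         GuildState([2.0], [10.0]), ref_params)
        Q = interaction_strength_matrix(comm)
        assert Q.Q[1, 0] == 0.0

    def test_guild_role_transpose_consistency(self, random_equilibria):
        # swapping the guilds (a symmetric relabeling) transposes Q
        for comm in random_equilibria(11, 3):
            Q = interaction_strength_matrix(comm)
            p = comm.params
            from dataclasses import replace
            swapped_params = replace(
                p, k_A=p.k_P, k_P=p.k_A, x_Amax=p.y_Pmax, y_Pmax=p.x_Amax,
                sigma_A=p.sigma_P, sigma_P=p.sigma_A)
            swapped = Community(comm.plants.copy(), comm.animals.copy(),
                                swapped_params)
            Qs = interaction_strength_matrix(swapped)
            assert np.allclose(Q.Q, Qs.Q.T, rtol=1e-10)

    def test_nonnegative(self, random_equilibria):
        for comm in random_equilibria(13, 2):
            assert np.all(interaction_strength_matrix(comm).Q >= 0)


class TestAnalyticJacobian:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        for _ in range(4):
            n, m = rng.integers(2, 6, size=2)
            p = ModelParams().with_kernels(sigma_C=0.4, sigma_m=0.6,
                                           sigma_A=1.2)
            comm = Community(
                GuildState(rng.normal(3, 1, n), rng.uniform(10, 300, n)),
                GuildState(rng.normal(2, 1, m), rng.uniform(10, 300, m)), p)
            kern = build_kernels(comm)
            A, P = comm.animals.densities, comm.plants.densities
            Ja = percapita_jacobian(kern, p, A, P)
            N = np.concatenate([A, P])
            d = n + m
            eps = 1e-6
            for col in range(d):
                Np, Nm = N.copy(), N.copy()
                Np[col] += eps
                Nm[col] -= eps
                fp = np.concatenate(growth_rates(kern, p, Np[:n], Np[n:]))
                fm = np.concatenate(growth_rates(kern, p, Nm[:n], Nm[n:]))
                assert np.allclose(Ja[:, col], (fp - fm) / (2 * eps),
                                   atol=1e-6)
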