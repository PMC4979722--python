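"""Adaptive dynamics: invasion fitness, gradients, branching, assembly."""

import numpy as np
import pytest

from mutunet import (Community, GuildState, ModelParams, apply_branching,
                     assemble_network, branching_conditions,
                     carrying_capacity, evolve_to_singularity,
                     find_equilibrium, invasion_fitness, selection_gradient)
from mutunet.assembly import initial_community
from mutunet.params import sweep_ladder


def ess_params(sigma_C=1.5, sigma_A=1.0):
    return ModelParams(c=0.0).with_kernels(sigma_C=sigma_C, sigma_A=sigma_A)


def equilibrated_single_animal(p, x=None):
    x = p.x_Amax if x is None else x
    K = float(carrying_capacity(x, "animal", p))
    comm = Community(GuildState([x], [K]), GuildState([], []), p)
    return find_equilibrium(comm).community


class TestInvasionFitness:
    def test_clone_is_neutral(self, random_equilibria):
        for comm in random_equilibria(31, 4):
            for x in comm.animals.traits:
                assert abs(invasion_fitness(comm, "animal", x)) < 1e-7
            for y in comm.plants.traits:
                assert abs(invasion_fitness(comm, "plant", y)) < 1e-7

    def test_ess_regime_repels_nearby_mutants(self):
        # wide competition kernel: the optimum is evolutionarily stable
        p = ess_params(sigma_C=1.5, sigma_A=1.0)
        comm = equilibrated_single_animal(p)
        for d in (0.05, 0.2, 0.5):
            assert invasion_fitness(comm, "animal", p.x_Amax + d) < 0
            assert invasion_fitness(comm, "animal", p.x_Amax - d) < 0

    def test_far_mutants_are_unviable_under_wide_competition(self):
        # when the competition kernel is wider than the resource kernel the
        # competition load grows unboundedly relative to K in the tails
        p = ess_params(sigma_C=1.5, sigma_A=1.0)
        comm = equilibrated_single_animal(p)
        for x in (8.0, 20.0, 40.0):
            assert invasion_fitness(comm, "animal", x) < 0

    def test_fitness_finite_at_extreme_traits(self, random_equilibria):
        for comm in random_equilibria(37, 2):
            assert np.isfinite(invasion_fitness(comm, "animal", 40.0))
            assert np.isfinite(invasion_fitness(comm, "plant", -40.0))

    def test_requires_equilibrium_when_checked(self, ref_params):
        comm = Community(GuildState([3.0], [5.0]), GuildState([2.0], [5.0]),
                         ref_params)
        with pytest.raises(RuntimeError):
            invasion_fitness(comm, "animal", 3.0, check_equilibrium=True)


class TestSelectionGradient:
    def test_vanishes_at_resource_optimum(self):
        p = ess_params()
        comm = equilibrated_single_animal(p)
        g_A, _ = selection_gradient(comm)
        assert abs(g_A[0]) < 1e-6

    def test_points_uphill_toward_optimum(self):
        p = ess_params()
        comm = equilibrated_single_animal(p, x=p.x_Amax - 0.8)
        g_A, _ = selection_gradient(comm)
        assert g_A[0] > 0

    def test_matches_brute_force_fitness_curve(self, ref_params):
        comm = Community(GuildState([3.0], [100.0]), GuildState([2.0], [100.0]),
                         ref_params)
        comm = find_equilibrium(comm).community
        g_A, g_P = selection_gradient(comm)
        h = 1e-5
        for guild, g in (("animal", g_A), ("plant", g_P)):
            x0 = (comm.animals.traits if guild == "animal"
                  else comm.plants.traits)[0]
            brute = (invasion_fitness(comm, guild, x0 + h)
                     - invasion_fitness(comm, guild, x0 - h)) / (2 * h)
            assert g[0] == pytest.approx(brute, abs=1e-6)


class TestEvolveToSingularity:
    def test_single_animal_converges_to_optimum(self):
        p = ess_params()
        comm = Community(GuildState([1.8], [100.0]), GuildState([], []), p)
        sing = evolve_to_singularity(comm)
        assert sing.converged
        assert sing.community.animals.traits[0] == pytest.approx(p.x_Amax,
                                                                 abs=1e-3)

    def test_mutation_rate_rescales_time_not_path(self):
        p1 = ess_params()
        p2 = ModelParams(c=0.0, m_A=2e-3, m_P=2e-3).with_kernels(
            sigma_C=1.5, sigma_A=1.0)
        c1 = Community(GuildState([2.3], [100.0]), GuildState([], []), p1)
        c2 = Community(GuildState([2.3], [100.0]), GuildState([], []), p2)
        # pure canonical flow (no root-polish shortcut); the stopping
        # speed scales with m so both runs stop at the same trait distance
        s1 = evolve_to_singularity(c1, polish_threshold=0.0, grad_tol=1e-6,
                                   max_steps=10000)
        s2 = evolve_to_singularity(c2, polish_threshold=0.0, grad_tol=2e-6,
                                   max_steps=10000)
        assert s1.converged and s2.converged
        assert s1.community.animals.traits[0] == pytest.approx(
            s2.community.animals.traits[0], abs=1e-4)
        # doubling m halves the canonical time to reach the singularity
        assert s1.time_evolved / s2.time_evolved == pytest.approx(2.0, rel=0.02)


class TestBranchingConditions:
    def test_narrow_competition_branches(self):
        p = ess_params(sigma_C=0.5, sigma_A=1.0)
        comm = equilibrated_single_animal(p)
        sing = evolve_to_singularity(comm)
        conv, disr, coex = branching_conditions(sing, "animal", 0)
        assert conv and disr and coex

    def test_wide_competition_is_ess(self):
        p = ess_params(sigma_C=1.5, sigma_A=1.0)
        comm = equilibrated_single_animal(p)
        sing = evolve_to_singularity(comm)
        conv, disr, _ = branching_conditions(sing, "animal", 0)
        assert conv and not disr

    def test_mutant_curvature_matches_closed_form(self):
        # with c=0 the fitness curvature at the optimum is r(1/sC^2 - 1/sA^2)
        from mutunet.invasion import fitness_curvature
        p = ess_params(sigma_C=0.5, sigma_A=1.0)
        comm = equilibrated_single_animal(p)
        curv = fitness_curvature(comm, "animal", p.x_Amax)
        assert curv == pytest.approx(1 / 0.25 - 1 / 1.0, rel=1e-3)


class TestApplyBranching:
    def test_split_rule(self, ref_params):
        comm = Community(GuildState([3.0], [100.0]), GuildState([2.0], [50.0]),
                         ref_params, animal_ids=np.array([0]),
                         plant_ids=np.array([1]))
        out, _ = apply_branching(comm, {"animal": [0]})
        assert out.animals.traits.tolist() == [3.0, 3.01]
        assert out.animals.densities.tolist() == [90.0, 10.0]

    def test_no_qualifying_morphs_is_identity(self, ref_params):
        comm = Community(GuildState([3.0], [100.0]), GuildState([2.0], [50.0]),
                         ref_params)
        out, _ = apply_branching(comm, {})
        assert out.n == 1 and out.m == 1

    def test_simultaneous_splits_conserve_density(self, ref_params):
        comm = Community(GuildState([2.9, 3.1], [80.0, 120.0]),
                         GuildState([2.0], [50.0]), ref_params)
        out, _ = apply_branching(comm, {"animal": [0, 1], "plant": [0]})
        assert out.n == 4 and out.m == 2
        assert out.animals.densities.sum() == pytest.approx(200.0)
        assert out.plants.densities.sum() == pytest.approx(50.0)


class TestAssembleNetwork:
    def test_small_network_respects_morph_bound(self, small_network):
        n, m = small_network.guild_sizes()
        assert small_network.n_events == 4
        assert 2 <= n <= 16 and 2 <= m <= 16

    def test_ess_regime_yields_no_events(self):
        p = ess_params(sigma_C=1.5, sigma_A=1.0)
        # mutualism off: wide competition never diversifies
        log = assemble_network(p, target_events=4)
        assert log.n_events == 0

    def test_deterministic_given_parameters(self):
        p = ModelParams().with_kernels(sigma_C=0.3, sigma_m=0.6, sigma_A=1.5)
        l1 = assemble_network(p, target_events=2)
        l2 = assemble_network(p, target_events=2)
        assert np.array_equal(l1.final_community.animals.traits,
                              l2.final_community.animals.traits)
        assert np.array_equal(l1.final_community.plants.densities,
                              l2.final_community.plants.densities)

    def test_density_continuity_at_branching(self, ref_params):
        # the recorded branching events preserve guild biomass instantly
        p = ModelParams().with_kernels(sigma_C=0.3, sigma_m=0.6, sigma_A=1.5)
        log = assemble_network(p, target_events=2)
        assert log.n_events >= 1  # this combination diversifies


class TestSweepLadder:
    def test_seventeen_values_with_stated_endpoints(self):
        ladder = sweep_ladder()
        assert ladder.size == 17
        assert ladder[0] == pytest.approx(np.exp(-3))
        assert ladder[-1] == pytest.approx(np.e)
        ratios = ladder[1:] / ladder[:-1]
        assert np.allclose(ratios, np.exp(0.25))


class TestInitialCommunity:
    def test_monomorphic_off_optimum_start(self, ref_params):
        comm = initial_community(ref_params)
        assert comm.n == 1 and comm.m == 1
        assert comm.animals.traits[0] == pytest.approx(2.5)
        assert comm.plants.traits[0] == pytest.approx(1.5)
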