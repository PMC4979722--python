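"""Stability metrics and the invasion-trial engine."""

import numpy as np
import pytest

from mutunet import (Community, GuildState, InvasionScenario, ModelParams,
                     carrying_capacity, disruptiveness, find_equilibrium,
                     interaction_strength_matrix, introduction_schedule,
                     invasibility, resilience, robustness,
                     run_invasion_trial, ensemble_invasion_record)
from mutunet.invasion import _alien_trait, default_glr_grid


def single_logistic_at_capacity(r=1.0):
    p = ModelParams(c=0.0, r_A=r)
    K = float(carrying_capacity(p.x_Amax, "animal", p))
    return Community(GuildState([p.x_Amax], [K]), GuildState([], []), p)


class TestResilience:
    def test_unit_rate_logistic_returns_zero(self):
        # J = -r = -1 at the logistic fixed point
        assert resilience(single_logistic_at_capacity(1.0)) == pytest.approx(
            0.0, abs=1e-5)

    def test_faster_return_raises_resilience(self):
        assert resilience(single_logistic_at_capacity(np.e)) == pytest.approx(
            1.0, abs=1e-5)

    def test_dominant_eigenvalue_is_largest_real_part(self):
        # two independent logistic morphs decaying at -r and -2r: the
        # dominant (slowest) mode sets RES = ln r
        p = ModelParams(c=0.0, sigma_C=0.2, r_A=0.5)
        x = np.array([3.0, -3.0])
        comm = Community(GuildState(x, carrying_capacity(x, "animal", p)),
                         GuildState([], []), p)
        comm = find_equilibrium(comm).community
        assert resilience(comm) == pytest.approx(np.log(0.5), abs=1e-3)

    def test_unstable_state_rejected(self, ref_params):
        comm = Community(GuildState([3.0], [10.0]), GuildState([2.0], [10.0]),
                         ref_params)
        with pytest.raises(ValueError):
            resilience(comm)


def brute_force_robustness(Q):
    """Independent exhaustive simulation of the removal cascade."""
    Q = np.asarray(Q, dtype=float)
    n, m = Q.shape
    total = n + m
    degree = np.concatenate([Q.sum(1), Q.sum(0)])
    order = sorted(range(total), key=lambda s: (-degree[s], s))
    rows, cols = set(range(n)), set(range(m))
    removed = 0
    for sp in order:
        if sp < n:
            if sp not in rows:
                continue
            rows.discard(sp)
        else:
            if sp - n not in cols:
                continue
            cols.discard(sp - n)
        removed += 1
        while True:
            dead_r = {i for i in rows if all(Q[i, j] == 0 for j in cols)}
            dead_c = {j for j in cols if all(Q[i, j] == 0 for i in rows)}
            if not dead_r and not dead_c:
                break
            rows -= dead_r
            cols -= dead_c
        if total - len(rows) - len(cols) > 0.5 * total:
            return removed / total
    return 1.0


class TestRobustness:
    def test_star_network_collapses_with_hub(self):
        for k in (3, 5, 8):
            Q = np.ones((1, k))
            assert robustness(Q) == pytest.approx(1 / (k + 1))

    def test_uniform_complete_two_by_two(self):
        assert robustness(np.ones((2, 2))) == pytest.approx(0.5)

    def test_matches_brute_force_on_small_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = rng.integers(1, 5)
            m = rng.integers(1, 5)
            Q = rng.integers(0, 4, size=(n, m)).astype(float)
            if Q.sum() == 0:
                continue
            assert robustness(Q) == brute_force_robustness(Q)

    def test_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            Q = rng.random((5, 6)) * (rng.random((5, 6)) < 0.5)
            if Q.sum() == 0:
                continue
            assert 0.0 < robustness(Q) <= 1.0


class TestDisruptiveness:
    def test_branching_regime_is_disruptive(self):
        p = ModelParams(c=0.0).with_kernels(sigma_C=0.5, sigma_A=1.0)
        comm = Community(GuildState([3.0], [400.0]), GuildState([], []), p)
        comm = find_equilibrium(comm).community
        assert disruptiveness(comm) > 0

    def test_ess_regime_is_stabilizing(self):
        p = ModelParams(c=0.0).with_kernels(sigma_C=1.5, sigma_A=1.0)
        comm = Community(GuildState([3.0], [400.0]), GuildState([], []), p)
        comm = find_equilibrium(comm).community
        assert disruptiveness(comm) < 0

    def test_sum_variant_scales_with_morph_count(self):
        p = ModelParams(c=0.0, sigma_C=0.2).with_kernels(sigma_C=0.2,
                                                         sigma_A=1.0)
        x = np.array([2.0, 4.0])
        comm = Community(GuildState(x, carrying_capacity(x, "animal", p)),
                         GuildState([], []), p)
        comm = find_equilibrium(comm).community
        mean = disruptiveness(comm, aggregate="mean")
        total = disruptiveness(comm, aggregate="sum")
        assert total == pytest.approx(2 * mean)


class TestIntroductionSchedule:
    def test_decreasing_mode_hand_example(self):
        assert introduction_schedule(4, 10.0) == [(0.0, 5.0), (5.0, 3.0),
                                                  (10.0, 2.0)]

    def test_five_equal_pulses(self):
        sched = introduction_schedule(5, 10.0)
        assert [t for t, _ in sched] == [0.0, 5.0, 10.0, 15.0, 20.0]
        assert all(a == pytest.approx(2.0) for _, a in sched)

    @pytest.mark.parametrize("mode", [1, 2, 3, 4, 5])
    def test_amounts_conserved(self, mode):
        total = 7.3
        sched = introduction_schedule(mode, total)
        assert sum(a for _, a in sched) == pytest.approx(total)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            introduction_schedule(6, 1.0)


@pytest.fixture(scope="module")
def native_pair():
    """A small 2+2 native community at its stable equilibrium."""
    p = ModelParams().with_kernels(sigma_C=0.4, sigma_m=0.6, sigma_A=1.2)
    comm = Community(GuildState([2.6, 3.4], [150.0, 150.0]),
                     GuildState([1.6, 2.4], [120.0, 120.0]), p)
    eq = find_equilibrium(comm)
    assert eq.converged
    return eq.community


class TestInvasionTrial:
    def test_clone_alien_is_nearly_neutral(self, native_pair):
        # an alien cloning the lowest-trait resident at tiny propagule size
        sc = InvasionScenario(rtv=0.0, glr=1.0, propagule_fraction=1e-3)
        out = run_invasion_trial(native_pair, sc)
        assert abs(out.INVn) < 0.01

    def test_traits_frozen_during_trial(self, native_pair):
        before = native_pair.animals.traits.copy()
        sc = InvasionScenario(rtv=0.5, glr=2.0)
        run_invasion_trial(native_pair, sc)
        assert np.array_equal(native_pair.animals.traits, before)

    def test_far_outside_alien_is_trivial(self, native_pair):
        sc = InvasionScenario(rtv=8.0, glr=1.0)  # far beyond native range
        out = run_invasion_trial(native_pair, sc)
        assert not out.success
        assert out.IMP < 1e-3

    def test_tiny_failed_propagule_leaves_natives_unchanged(self, native_pair):
        sc = InvasionScenario(rtv=8.0, glr=1.0, propagule_fraction=1e-6)
        out = run_invasion_trial(native_pair, sc)
        assert out.IMP < 1e-6

    def test_pulse_splitting_neutral_for_clone(self, native_pair):
        outs = [run_invasion_trial(
            native_pair, InvasionScenario(rtv=0.0, propagule_fraction=1e-3,
                                          mode=mode))
            for mode in (1, 5)]
        assert outs[0].INVn == pytest.approx(outs[1].INVn, abs=5e-3)

    def test_alien_trait_mapping(self, native_pair):
        lo = native_pair.animals.traits.min()
        hi = native_pair.animals.traits.max()
        assert _alien_trait(native_pair, 0.0) == pytest.approx(lo)
        assert _alien_trait(native_pair, 1.0) == pytest.approx(hi)
        assert _alien_trait(native_pair, 0.5) == pytest.approx((lo + hi) / 2)


class TestInvasibility:
    def test_proportion_on_lattice(self, native_pair):
        v = invasibility(native_pair)
        assert 0.0 <= v <= 1.0
        assert v * 9 == pytest.approx(round(v * 9))

    def test_glr_grid_log_symmetric_with_unit_center(self):
        g = default_glr_grid()
        assert g[0] == pytest.approx(0.2)
        assert g[-1] == pytest.approx(5.0)
        assert g[4] == pytest.approx(1.0)


class TestEnsembleRecord:
    def test_reference_alien_uses_density_weighted_mean_trait(self):
        p = ModelParams().with_kernels(sigma_C=0.4, sigma_m=0.6, sigma_A=1.2)
        comm = Community(GuildState([2.0, 4.0], [100.0, 100.0]),
                         GuildState([1.6, 2.4], [120.0, 120.0]), p)
        # equal densities degenerate to the arithmetic mean = rtv 0.5
        assert _alien_trait(comm, 0.5) == pytest.approx(3.0)

    def test_record_reproducible(self, native_pair):
        a = ensemble_invasion_record(native_pair)
        b = ensemble_invasion_record(native_pair)
        assert a.INVn == b.INVn and a.IMP == b.IMP
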