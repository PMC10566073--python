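"""Sparrow search optimizer: strategy primitives and the full loop."""

import numpy as np
import pytest

from msxfgp.mssa import (
    MSSAConfig,
    SearchSpace,
    adaptive_rates,
    check_early_stop,
    elite_merge,
    init_population_chaotic,
    levy_step,
    logistic_chaos_sequence,
    mantegna_sigma,
    optimize,
    round_half_away,
    update_discoverers,
    update_followers,
    update_vigilantes,
)


def box(lb, ub, dim):
    return SearchSpace(np.full(dim, float(lb)), np.full(dim, float(ub)), np.zeros(dim, bool))


class TestChaosInit:
    def test_logistic_map_hand_iterates(self):
        np.testing.assert_allclose(
            logistic_chaos_sequence(3, mu=4.0, c0=0.2),
            [0.64, 0.9216, 0.28901376],
            rtol=0,
            atol=1e-12,
        )

    def test_map_of_half_hits_one_then_zero(self):
        np.testing.assert_array_equal(
            logistic_chaos_sequence(2, mu=4.0, c0=0.5), [1.0, 0.0]
        )

    @pytest.mark.parametrize("c0", [0.0, 1.0, -0.1, 1.5])
    def test_seed_outside_open_interval_rejected(self, c0):
        with pytest.raises(ValueError):
            logistic_chaos_sequence(3, mu=4.0, c0=c0)

    def test_initial_positions_within_bounds_and_deterministic(self):
        space = SearchSpace([-3.0, 0.0], [2.0, 10.0], [False, True])
        a = init_population_chaotic(space, 50, np.random.default_rng(7))
        b = init_population_chaotic(space, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        assert (a >= space.lower_bounds).all() and (a <= space.upper_bounds).all()

    def test_identity_affine_map_returns_chaos_matrix_in_unit_box(self):
        space = box(0, 1, 4)
        c = init_population_chaotic(space, 200, np.random.default_rng(0))
        assert ((0 <= c) & (c <= 1)).all()

    def test_chaos_samples_are_bimodal_toward_interval_ends(self):
        # the mu=4 invariant density is arcsine: mass piles up near 0 and 1
        c = init_population_chaotic(box(0, 1, 50), 200, np.random.default_rng(3))
        flat = c.ravel()
        edges = ((flat < 0.1) | (flat > 0.9)).mean()
        middle = ((flat > 0.45) & (flat < 0.55)).mean()
        assert edges > middle
        assert flat.min() < 0.05 and flat.max() > 0.95


class TestSchedules:
    def test_endpoints(self):
        cfg = MSSAConfig(max_iterations=20)
        assert adaptive_rates(0, cfg) == (cfg.pd_start, cfg.sd_start)
        assert adaptive_rates(19, cfg) == (cfg.pd_end, cfg.sd_end)

    def test_midpoint_interpolation(self):
        cfg = MSSAConfig(max_iterations=101, pd_start=0.7, pd_end=0.3)
        pd, _ = adaptive_rates(50, cfg)
        assert pd == pytest.approx(0.5)

    def test_monotone_directions(self):
        cfg = MSSAConfig(max_iterations=30)
        pds, sds = zip(*(adaptive_rates(t, cfg) for t in range(30)))
        assert all(a >= b for a, b in zip(pds, pds[1:]))
        assert all(a <= b for a, b in zip(sds, sds[1:]))


class TestDiscovererUpdate:
    def _run(self, positions, ranks, seed, st=0.8, m=100):
        cfg = MSSAConfig(max_iterations=m, alert_threshold=st)
        space = box(-10, 10, positions.shape[1])
        return update_discoverers(
            positions, np.asarray(ranks), cfg, space, np.random.default_rng(seed)
        )

    def _find_seed(self, below_st):
        # locate a seed whose first uniform draw lands in the wanted branch
        for seed in range(100):
            r = np.random.default_rng(seed).uniform()
            if (r < 0.8) == below_st:
                return seed
        raise AssertionError("no seed found")

    def test_safe_branch_is_multiplicative_decay(self):
        seed = self._find_seed(below_st=True)
        rng = np.random.default_rng(seed)
        rng.uniform()
        alpha = 1.0 - rng.random()
        out = self._run(np.array([[2.0, -4.0]]), [1], seed)
        np.testing.assert_allclose(
            out[0], np.array([2.0, -4.0]) * np.exp(-1.0 / (alpha * 100))
        )

    def test_rank_one_alpha_one_matches_hand_value(self):
        # X * exp(-i/(alpha*M)) at i=1, alpha=1, M=100 -> 2 * exp(-0.01)
        assert 2.0 * np.exp(-0.01) == pytest.approx(1.9801, abs=1e-4)

    def test_origin_is_fixed_under_safe_branch(self):
        seed = self._find_seed(below_st=True)
        out = self._run(np.zeros((3, 2)), [1, 2, 3], seed)
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_alarm_branch_adds_scalar_per_sparrow(self):
        seed = self._find_seed(below_st=False)
        pos = np.array([[1.0, 2.0], [0.5, -0.5]])
        out = self._run(pos, [1, 2], seed)
        shift = out - pos
        # Q broadcasts over dimensions: each row shifts by one scalar
        np.testing.assert_allclose(shift[:, 0], shift[:, 1])

    def test_empty_set_is_noop(self):
        out = self._run(np.empty((0, 2)), [], 0)
        assert out.shape == (0, 2)


class TestFollowerUpdate:
    def test_pseudo_inverse_identity_for_sign_rows(self):
        # A^T (A A^T)^{-1} == A^T / dim for every +/-1 row
        rng = np.random.default_rng(0)
        for _ in range(1000):
            dim = int(rng.integers(1, 12))
            a = rng.choice([-1.0, 1.0], size=(1, dim))
            pinv = a.T @ np.linalg.inv(a @ a.T)
            np.testing.assert_array_equal(pinv, a.T / dim)

    def test_follower_at_best_discoverer_stays(self):
        space = box(-10, 10, 3)
        x_p = np.array([1.0, -2.0, 0.5])
        out = update_followers(
            x_p[None, :], np.array([2]), x_p, np.zeros(3), 10, space,
            np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out[0], x_p)

    def test_starving_follower_is_scaled_exponential_of_worst_gap(self):
        space = box(-10, 10, 2)
        pos = np.array([[1.0, 2.0]])
        x_w = np.array([3.0, -1.0])
        rank = 9
        rng = np.random.default_rng(4)
        out = update_followers(
            pos, np.array([rank]), np.zeros(2), x_w, 10, space,
            np.random.default_rng(4),
        )
        q = rng.standard_normal()
        np.testing.assert_allclose(out[0], np.clip(q * np.exp((x_w - pos[0]) / rank**2), -10, 10))

    def test_results_respect_bounds(self):
        space = box(-1, 1, 4)
        rng = np.random.default_rng(9)
        pos = rng.uniform(-1, 1, size=(20, 4))
        out = update_followers(
            pos, np.arange(11, 31), np.zeros(4), pos[0], 30, space, rng
        )
        assert (out >= -1).all() and (out <= 1).all()


class TestLevyStep:
    def test_mantegna_scale_at_beta_1_5(self):
        assert mantegna_sigma(1.5) == pytest.approx(0.696575, abs=1e-5)

    def test_steps_are_heavy_tailed_relative_to_gaussian(self):
        rng = np.random.default_rng(12)
        s = levy_step(100_000, 1.5, rng)
        g = rng.normal(0.0, mantegna_sigma(1.5), 100_000)
        kurt = lambda x: np.mean((x - x.mean()) ** 4) / np.var(x) ** 2
        assert kurt(s) > 10 * kurt(g)
        assert np.abs(s).max() > 10 * np.abs(g).max()

    @pytest.mark.parametrize("beta", [1.01, 1.5, 2.0])
    def test_finite_for_valid_exponents(self, beta):
        s = levy_step(1000, beta, np.random.default_rng(1))
        assert np.isfinite(s).all()

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            levy_step(5, 1.0, np.random.default_rng(0))


class TestVigilanteUpdate:
    def _space(self):
        return box(-10, 10, 2)

    def test_vigilante_at_best_position_stays_when_not_best_fitness(self):
        x_best = np.array([1.0, 1.0])
        out = update_vigilantes(
            x_best[None, :], np.array([0.5]), x_best, 1.0, 0.0,
            MSSAConfig(), self._space(), np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out[0], x_best)

    def test_best_fitness_vigilante_at_best_position_stays(self):
        x_best = np.array([2.0, -1.0])
        out = update_vigilantes(
            x_best[None, :], np.array([1.0]), x_best, 1.0, 0.0,
            MSSAConfig(), self._space(), np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out[0], x_best)

    def test_best_fitness_branch_moves_along_displacement(self):
        # f_i = f_g, f_w = f_g - 1: step = k * (X - X_best) / (1 + eps)
        x_best = np.zeros(2)
        pos = np.array([[1.0, 0.0]])
        rng = np.random.default_rng(8)
        k = np.random.default_rng(8).uniform(-1, 1)
        out = update_vigilantes(
            pos, np.array([1.0]), x_best, 1.0, 0.0,
            MSSAConfig(), self._space(), rng,
        )
        np.testing.assert_allclose(out[0], [k * 1.0 / (1.0 + 1e-8), 0.0])


class TestEliteMerge:
    def test_zero_rate_passes_population_through(self):
        pos = np.arange(6.0).reshape(3, 2)
        fit = np.array([1.0, 2.0, 3.0])
        out_pos, out_fit, _, _ = elite_merge(
            pos, fit, np.empty((0, 2)), np.empty(0), 3, 0
        )
        np.testing.assert_array_equal(out_pos, pos)
        np.testing.assert_array_equal(out_fit, fit)

    def test_fitter_archived_particle_survives(self):
        pos = np.zeros((3, 1))
        fit = np.array([1.0, 2.0, 3.0])
        arch_pos = np.array([[9.0]])
        arch_fit = np.array([10.0])
        out_pos, out_fit, new_ap, new_af = elite_merge(pos, fit, arch_pos, arch_fit, 3, 1)
        assert 10.0 in out_fit
        assert new_af.tolist() == [10.0]

    def test_enumerated_merge_keeps_top_n(self):
        pos = np.array([[1.0], [2.0], [3.0]])
        fit = np.array([1.0, 2.0, 3.0])
        out_pos, out_fit, _, _ = elite_merge(
            pos, fit, np.array([[2.5]]), np.array([2.5]), 3, 1
        )
        assert sorted(out_fit.tolist(), reverse=True) == [3.0, 2.5, 2.0]

    def test_full_elitism_never_worsens_fitness_multiset(self):
        rng = np.random.default_rng(2)
        n = 5
        pos = rng.normal(size=(n, 2))
        fit = rng.normal(size=n)
        arch_pos, arch_fit = np.empty((0, 2)), np.empty(0)
        prev = np.sort(fit)
        for _ in range(20):
            new_pos = rng.normal(size=(n, 2))
            new_fit = rng.normal(size=n)
            # full archive: elite_size = N
            pos, fit, arch_pos, arch_fit = elite_merge(
                new_pos, new_fit, pos, fit, n, n
            )
            cur = np.sort(fit)
            assert (cur >= prev).all()
            prev = cur


class TestEarlyStop:
    def test_threshold_semantics(self):
        assert not check_early_stop(0, 25)
        assert not check_early_stop(24, 25)
        assert check_early_stop(25, 25)

    def test_constant_objective_stops_after_exactly_patience_iterations(self):
        space = box(0, 10, 1)
        cfg = MSSAConfig(population_size=10, max_iterations=40, early_stop_patience=20, seed=0)
        res = optimize(lambda x: 1.0, space, cfg)
        assert res.stopped_early
        assert len(res.history) == 20
        assert res.history[-1].stagnation_counter == 20


class TestOptimize:
    def test_sphere_converges_near_origin(self):
        space = box(-10, 10, 5)
        cfg = MSSAConfig(
            population_size=30, max_iterations=100, early_stop_patience=100, seed=1
        )
        res = optimize(lambda x: -float(np.sum(x * x)), space, cfg)
        assert res.best_fitness >= -1e-3
        first = res.history[0].best_fitness
        assert res.best_fitness >= first

    def test_shifted_quadratic_finds_argmax(self):
        space = box(0, 10, 1)
        cfg = MSSAConfig(population_size=20, max_iterations=50, early_stop_patience=50, seed=2)
        res = optimize(lambda x: -((x[0] - 3.0) ** 2), space, cfg)
        assert abs(res.best_position[0] - 3.0) <= 0.01

    def test_history_monotone_and_bounds_respected(self):
        space = SearchSpace([-5.0, 0.0, -2.0], [5.0, 4.0, 2.0], [False, True, False])
        seen = []

        def objective(x):
            seen.append(x.copy())
            return -float(np.sum((x - 1.0) ** 2))

        cfg = MSSAConfig(population_size=15, max_iterations=30, seed=3)
        res = optimize(objective, space, cfg)
        best = [r.best_fitness for r in res.history]
        assert all(b >= a for a, b in zip(best, best[1:]))
        evaluated = np.array(seen)
        assert (evaluated >= space.lower_bounds - 1e-12).all()
        assert (evaluated <= space.upper_bounds + 1e-12).all()
        # integer-masked dimension is always evaluated at whole numbers
        assert np.all(evaluated[:, 1] == np.round(evaluated[:, 1]))

    def test_same_seed_gives_identical_trajectories(self):
        space = box(-10, 10, 4)
        cfg = MSSAConfig(population_size=12, max_iterations=25, seed=42)
        f = lambda x: -float(np.sum(np.abs(x)))
        a = optimize(f, space, cfg)
        b = optimize(f, space, cfg)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history

    def test_iteration_budget_is_an_upper_bound(self):
        space = box(-1, 1, 2)
        cfg = MSSAConfig(population_size=8, max_iterations=15, seed=0)
        res = optimize(lambda x: float(x[0]), space, cfg)
        assert len(res.history) <= 15

    def test_objective_error_carries_context(self):
        from msxfgp.mssa import ObjectiveError

        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(ObjectiveError, match="iteration -1, particle 0"):
            optimize(bad, box(0, 1, 1), MSSAConfig(population_size=5, max_iterations=3))


class TestSearchSpaceHelpers:
    def test_round_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away(np.array([6.5, -6.5, 2.4, -2.4, 0.5])),
            [7.0, -7.0, 2.0, -2.0, 1.0],
        )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace([0.0, 1.0], [1.0, 1.0], [False, False])

    def test_round_integers_only_touches_masked_dims(self):
        space = SearchSpace([0.0, 0.0], [10.0, 10.0], [False, True])
        out = space.round_integers(np.array([3.7, 3.7]))
        np.testing.assert_array_equal(out, [3.7, 4.0])
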