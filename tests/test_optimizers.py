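"""Unit tests for the continuous RBMO/IRBMO update rules and run loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magpiefs.optimizers import (
    ConfigurationError,
    OptimizerConfig,
    cf_factor,
    clamp,
    compensation_elite_update,
    compensation_reserve_update,
    elite_brownian_update,
    elite_mean_update,
    greedy_select,
    hunt_cauchy_update,
    hunt_levy_update,
    initialize_population,
    levy_step,
    mantegna_sigma,
    prey_update,
    run_optimizer,
    search_update,
)


class TestConfig:
    def test_small_population_rejected(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(dim=2, pop_size=3)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(dim=2, lower_bound=1.0, upper_bound=0.0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(dim=2, behavior_switch=1.5)


class TestInitialization:
    def test_degenerate_bounds_collapse(self):
        cfg = OptimizerConfig(dim=3, lower_bound=0.5, upper_bound=0.5, pop_size=5)
        state = initialize_population(cfg, np.random.default_rng(0))
        assert np.all(state.positions == 0.5)

    def test_seed_determinism(self):
        cfg = OptimizerConfig(dim=4, pop_size=6, seed=9)
        a = initialize_population(cfg, np.random.default_rng(9)).positions
        b = initialize_population(cfg, np.random.default_rng(9)).positions
        np.testing.assert_array_equal(a, b)

    def test_positions_in_bounds_and_elite_pool_shape(self):
        cfg = OptimizerConfig(dim=3, lower_bound=-2, upper_bound=5, pop_size=8)
        state = initialize_population(cfg, np.random.default_rng(1), lambda x: float(x.sum()))
        assert np.all(state.positions >= -2) and np.all(state.positions <= 5)
        assert state.elite_pool.shape == (4, 3)
        top3 = np.sort(state.fitness)[:3]
        np.testing.assert_allclose(
            np.sort([float(f) for f in state.elite_pool[:3].sum(axis=1)]),
            np.sort(top3),
        )


class TestCfFactor:
    @pytest.mark.parametrize("t,T,expected", [(0, 100, 1.0), (100, 100, 0.0), (50, 100, 0.5)])
    def test_endpoints_and_midpoint(self, t, T, expected):
        assert cf_factor(t, T) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        T = 200
        vals = [cf_factor(t, T) for t in range(T + 1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t,T", [(5, 4), (-1, 4), (1, 0)])
    def test_domain_errors(self, t, T):
        with pytest.raises(ValueError):
            cf_factor(t, T)


class TestLevy:
    def test_mantegna_sigma_value(self):
        # (Γ(1+β)·sin(πβ/2) / (Γ((1+β)/2)·β·2^((β−1)/2)))^(1/β) at β = 1.5
        assert mantegna_sigma(1.5) == pytest.approx(0.696575, abs=1e-4)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.5])
    def test_beta_domain(self, beta):
        with pytest.raises(ValueError):
            levy_step(beta, np.random.default_rng(0))

    def test_determinism(self):
        a = [levy_step(1.5, np.random.default_rng(3)) for _ in range(5)]
        b = [levy_step(1.5, np.random.default_rng(3)) for _ in range(5)]
        assert a == b

    def test_heavy_tail_exceeds_gaussian(self, rng):
        from scipy import stats

        draws = np.array([levy_step(1.5, rng) for _ in range(100_000)])
        p_emp = np.mean(np.abs(draws) > 10)
        sigma = mantegna_sigma(1.5)
        p_gauss = 2 * stats.norm.sf(10, scale=sigma)  # ~1e-46
        assert p_emp > 1e-4
        assert p_emp > 1e6 * p_gauss


class TestUpdateRuleFixedPoints:
    """With stochastic draws forced to zero (or degenerate geometry) every
    update collapses to a known point."""

    def test_search_zero_rand_is_identity(self):
        x = np.array([0.3, 0.7])
        out = search_update(x, np.array([1.0, 1.0]), np.array([0.0, 0.0]), rand=0.0)
        np.testing.assert_array_equal(out, x)

    def test_search_collapsed_population(self):
        x = np.array([0.4, 0.4])
        out = search_update(x, x, x, rand=0.77)
        np.testing.assert_array_equal(out, x)

    def test_search_hand_arithmetic_with_clamp(self):
        out = search_update(
            np.zeros(2), np.array([0.5, 0.5]), np.array([1.0, 1.0]), rand=1.0
        )
        np.testing.assert_allclose(out, [-0.5, -0.5])
        np.testing.assert_allclose(clamp(out, np.zeros(2), np.ones(2)), [0.0, 0.0])

    def test_prey_cf_zero_returns_food(self):
        food = np.array([0.2, 0.9])
        out = prey_update(food, np.array([1.0, 0.0]), np.array([0.0, 1.0]), cf=0.0, rand=0.6)
        np.testing.assert_array_equal(out, food)

    def test_prey_hand_arithmetic(self):
        out = prey_update(
            np.array([1.0, 1.0]), np.zeros(2), np.array([0.5, 0.5]), cf=0.5, rand=1.0
        )
        np.testing.assert_allclose(out, [0.75, 0.75])

    def test_elite_mean_degenerate_difference(self):
        x1 = np.array([1.0, 0.0])
        xeq = np.array([0.5, 0.5])
        np.testing.assert_array_equal(elite_mean_update(x1, xeq, xeq, rand=0.9), x1)

    def test_elite_mean_hand_arithmetic_with_clamp(self):
        out = elite_mean_update(
            np.array([1.0, 0.0]), np.array([0.5, 0.5]), np.array([0.0, 1.0]), rand=0.5
        )
        np.testing.assert_allclose(out, [1.25, -0.25])
        np.testing.assert_allclose(clamp(out, np.zeros(2), np.ones(2)), [1.0, 0.0])

    def test_elite_brownian_rb_zero(self):
        rs = np.array([0.1, 0.2])
        out = elite_brownian_update(rs, np.ones(2), np.zeros(2), rb=np.zeros(2), rand=0.4)
        np.testing.assert_array_equal(out, rs)

    def test_hunt_cauchy_cv_zero_and_degenerate(self):
        best = np.array([0.6, 0.6])
        assert np.array_equal(hunt_cauchy_update(best, np.ones(2), np.zeros(2), cv=0.0), best)
        xi = np.array([0.3, 0.3])
        assert np.array_equal(hunt_cauchy_update(best, xi, xi, cv=2.5), best)

    def test_hunt_levy_degenerate_collapses_to_origin(self):
        best = np.array([0.4, 0.8])
        out = hunt_levy_update(best, best, levy=3.0, rand=0.0, moderator=0.7)
        np.testing.assert_array_equal(out, np.zeros(2))
        np.testing.assert_array_equal(clamp(out, np.full(2, 0.1), np.ones(2)), np.full(2, 0.1))

    def test_compensation_reserve_identical_agents_is_identity(self):
        x = np.array([0.5, 0.1])
        pair = np.array([0.9, 0.9])
        np.testing.assert_array_equal(
            compensation_reserve_update(x, a=0.3, rand=0.8, x_idx1=pair, x_idx2=pair), x
        )

    def test_compensation_elite_cf_zero_is_identity(self):
        x = np.array([0.2, 0.2])
        out = compensation_elite_update(
            x, cf=0.0, rs_draw=np.ones(2), rand=0.5, lb=np.zeros(2), ub=np.ones(2), e=1.3
        )
        np.testing.assert_array_equal(out, x)


class TestGreedySelect:
    @pytest.mark.parametrize(
        "fa,fb,keep_new",
        [(0.5, 0.3, True), (0.3, 0.5, False), (0.4, 0.4, False)],
    )
    def test_retention(self, fa, fb, keep_new):
        xa, xb = np.zeros(2), np.ones(2)
        pos, fit = greedy_select(xa, fa, xb, fb)
        if keep_new:
            assert fit == fb and np.array_equal(pos, xb)
        else:
            assert fit == fa and np.array_equal(pos, xa)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            greedy_select(np.zeros(1), np.nan, np.ones(1), 0.1)


def sphere(x):
    return float(np.sum(x * x))


class TestRunOptimizer:
    @pytest.mark.parametrize("variant", ["rbmo", "irbmo"])
    def test_curve_monotone_and_in_bounds(self, variant):
        cfg = OptimizerConfig(dim=4, lower_bound=-5, upper_bound=5, pop_size=10, max_iter=30, seed=2)
        tr = run_optimizer(sphere, cfg, variant)
        assert np.all(np.diff(tr.curve) <= 0)
        assert np.all(tr.best_position >= -5) and np.all(tr.best_position <= 5)
        assert tr.curve[0] >= tr.best_fitness == tr.curve[-1]

    @pytest.mark.parametrize("variant", ["rbmo", "irbmo"])
    def test_seed_determinism(self, variant):
        cfg = OptimizerConfig(dim=3, lower_bound=-2, upper_bound=2, pop_size=8, max_iter=20, seed=5)
        a = run_optimizer(sphere, cfg, variant)
        b = run_optimizer(sphere, cfg, variant)
        np.testing.assert_array_equal(a.curve, b.curve)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_irbmo_solves_sphere(self):
        # heavily contracted elite moves should locate the interior optimum
        for seed in range(10):
            cfg = OptimizerConfig(
                dim=5, lower_bound=-10, upper_bound=10, pop_size=30, max_iter=100, seed=seed
            )
            assert run_optimizer(sphere, cfg, "irbmo").best_fitness < 1e-3

    def test_objective_exception_aborts_with_context(self):
        def bad(x):
            raise RuntimeError("boom")

        cfg = OptimizerConfig(dim=2, pop_size=4, max_iter=2, seed=0)
        with pytest.raises(RuntimeError):
            run_optimizer(bad, cfg, "irbmo")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            run_optimizer(sphere, OptimizerConfig(dim=2), "sparrow")


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_cf_factor_bounded(t):
    assert 0.0 <= cf_factor(t, 10_000) <= 1.0
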