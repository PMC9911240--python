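"""Unit and property tests for the continuous squirrel search optimizer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import squirrelselect as ss
from squirrelselect.benchmarks import sphere
from squirrelselect.ssa import GlideSample, assign_roles, season_threshold


def small_config(**kw):
    defaults = dict(
        n_squirrels=6, n_acorn=2, lower_bound=-5.0, upper_bound=5.0, max_iterations=10, seed=0
    )
    defaults.update(kw)
    return ss.SSAConfig(**defaults)


class TestConfig:
    def test_role_counts_must_fit_population(self):
        with pytest.raises(ValueError, match="population size"):
            ss.SSAConfig(n_squirrels=4, n_hickory=1, n_acorn=3)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError, match="lower_bound"):
            ss.SSAConfig(lower_bound=1.0, upper_bound=1.0)

    def test_predator_prob_range(self):
        with pytest.raises(ValueError, match="predator_prob"):
            ss.SSAConfig(predator_prob=1.5)


class TestInitialization:
    def test_forced_midpoint_draws(self, scripted_rng):
        cfg = small_config(lower_bound=0.0, upper_bound=1.0)
        rng = scripted_rng(uniforms=[0.5] * (6 * 3))
        pop = ss.initialize_population(cfg, sphere, dim=3, rng=rng)
        assert np.allclose(pop.positions, 0.5)

    def test_containment_and_shape_and_determinism(self):
        cfg = ss.SSAConfig(n_squirrels=50, lower_bound=-2.0, upper_bound=3.0, seed=7)
        pop1 = ss.initialize_population(cfg, sphere, dim=10)
        pop2 = ss.initialize_population(cfg, sphere, dim=10)
        assert pop1.positions.shape == (50, 10)
        assert np.all(pop1.positions >= -2.0) and np.all(pop1.positions <= 3.0)
        np.testing.assert_array_equal(pop1.positions, pop2.positions)

    def test_roles_by_fitness_rank(self):
        cfg = small_config()
        pop = ss.initialize_population(cfg, sphere, dim=2)
        assert np.sum(pop.roles == "hickory") == 1
        assert np.sum(pop.roles == "acorn") == 2
        hickory = pop.indices_of("hickory")[0]
        assert pop.fitness[hickory] == pop.fitness.min()
        acorn_fit = pop.fitness[pop.indices_of("acorn")]
        normal_fit = pop.fitness[pop.indices_of("normal")]
        assert acorn_fit.max() <= normal_fit.min()

    def test_nonfinite_fitness_names_the_squirrel(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="squirrel 0"):
            ss.initialize_population(cfg, lambda x: np.nan, dim=2)


class TestGlide:
    @pytest.mark.parametrize(
        "forced_cl, tan_phi, distance",
        [(0.675, 0.6 / 0.675, 0.5), (1.5, 0.4, 8.0 / (0.4 * 18.0))],
    )
    def test_closed_form_endpoints(self, scripted_rng, forced_cl, tan_phi, distance):
        cfg = small_config()
        unit = (forced_cl - 0.675) / (1.5 - 0.675)
        glide = ss.sample_glide(cfg, scripted_rng(uniforms=[unit]))
        assert glide.lift == pytest.approx(forced_cl)
        assert glide.tan_phi == pytest.approx(tan_phi)
        assert glide.distance == pytest.approx(distance)
        # tan_phi is exactly drag / lift
        assert glide.tan_phi == glide.drag / glide.lift

    def test_distance_always_in_documented_interval(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        d = np.array([ss.sample_glide(cfg, rng).distance for _ in range(1000)])
        assert d.min() >= 0.5 and d.max() <= 1.1112


class TestUpdates:
    def test_fixed_point_at_target(self, scripted_rng):
        cfg = small_config(lower_bound=0.0, upper_bound=10.0)
        glide = GlideSample(1.0, 0.6, 0.6, 0.8)
        new = ss.update_acorn_towards_hickory(
            [2.0, 2.0], [2.0, 2.0], glide, cfg, scripted_rng(uniforms=[0.9])
        )
        np.testing.assert_allclose(new, [2.0, 2.0])

    def test_hand_evaluated_glide_step(self, scripted_rng):
        cfg = small_config(lower_bound=0.0, upper_bound=10.0)
        glide = GlideSample(1.0, 0.6, 0.6, 0.5)
        new = ss.update_acorn_towards_hickory(
            [1.0], [3.0], glide, cfg, scripted_rng(uniforms=[0.9])
        )
        # 1.0 + 0.5 * 1.9 * (3.0 - 1.0) = 2.9
        np.testing.assert_allclose(new, [2.9])

    def test_step_clamps_to_upper_bound(self, scripted_rng):
        cfg = small_config(lower_bound=0.0, upper_bound=1.5)
        glide = GlideSample(1.0, 0.6, 0.6, 1.0)
        new = ss.update_normal_towards_acorn(
            [0.0], [1.0], glide, cfg, scripted_rng(uniforms=[0.9])
        )
        # raw step 0 + 1.0 * 1.9 * 1.0 = 1.9, clipped at 1.5
        np.testing.assert_allclose(new, [1.5])

    def test_predator_branch_relocates_uniformly(self, scripted_rng):
        cfg = small_config(lower_bound=0.0, upper_bound=10.0, predator_prob=1.0)
        glide = GlideSample(1.0, 0.6, 0.6, 0.5)
        new = ss.update_normal_towards_hickory(
            [9.0, 9.0], [1.0, 1.0], glide, cfg, scripted_rng(uniforms=[0.3, 0.25, 0.75])
        )
        # relocation ignores both positions entirely
        np.testing.assert_allclose(new, [2.5, 7.5])

    def test_dimension_mismatch_is_an_error(self, scripted_rng):
        cfg = small_config()
        glide = GlideSample(1.0, 0.6, 0.6, 0.5)
        with pytest.raises(ValueError, match="dimension mismatch"):
            ss.update_acorn_towards_hickory([1.0, 2.0], [1.0], glide, cfg, scripted_rng())

    @settings(derandomize=True, max_examples=50)
    @given(
        pos=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        target=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        unit_cl=st.floats(0, 1, exclude_max=True),
        r=st.floats(0, 1, exclude_max=True),
    )
    def test_updates_always_stay_in_bounds(self, pos, target, unit_cl, r):
        from conftest import ScriptedRNG

        cfg = small_config()
        glide = ss.sample_glide(cfg, ScriptedRNG(uniforms=[unit_cl]))
        rng = ScriptedRNG(uniforms=[r, 0.1, 0.5, 0.9])
        new = ss.update_normal_towards_hickory(pos, target, glide, cfg, rng)
        assert np.all(new >= -5.0) and np.all(new <= 5.0)


class TestSeason:
    def test_zero_distance_at_coincidence(self):
        assert ss.seasonal_constant([[1.0, 2.0]], [1.0, 2.0])[0] == 0.0

    def test_euclidean_three_four_five(self):
        np.testing.assert_allclose(ss.seasonal_constant([[0.0, 0.0]], [3.0, 4.0]), [5.0])

    def test_translation_invariance(self):
        base = ss.seasonal_constant([[1.0, -2.0]], [4.0, 2.0])
        shifted = ss.seasonal_constant([[11.0, 8.0]], [14.0, 12.0])
        np.testing.assert_allclose(base, shifted)

    def test_empty_acorn_set_is_an_error(self):
        with pytest.raises(ValueError, match="acorn"):
            ss.seasonal_constant(np.empty((0, 2)), [0.0, 0.0])

    def test_threshold_shrinks_with_iteration(self):
        values = [season_threshold(t, 100) for t in range(0, 101, 10)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(1e-5)


class TestWinterRelocation:
    def test_containment_over_many_draws(self):
        cfg = small_config(lower_bound=-1.0, upper_bound=2.0)
        rng = np.random.default_rng(3)
        for _ in range(200):
            v = ss.winter_relocate(cfg, rng, dim=4)
            assert np.all(v >= -1.0) and np.all(v <= 2.0)

    def test_deterministic_under_seed(self):
        cfg = small_config()
        v1 = ss.winter_relocate(cfg, np.random.default_rng(5), dim=6)
        v2 = ss.winter_relocate(cfg, np.random.default_rng(5), dim=6)
        np.testing.assert_array_equal(v1, v2)

    def test_degenerate_bounds_collapse_to_lower(self):
        cfg = small_config()
        cfg.lower_bound = 3.0
        cfg.upper_bound = 3.0  # bypasses construction-time validation on purpose
        np.testing.assert_allclose(ss.winter_relocate(cfg, np.random.default_rng(0), dim=3), 3.0)


class TestRunLoop:
    def test_zero_iterations_returns_initial_best(self):
        cfg = small_config(max_iterations=0, seed=11)
        pop, trace = ss.run_ssa(cfg, sphere, dim=3)
        init = ss.initialize_population(cfg, sphere, dim=3)
        assert pop.best_fitness == init.fitness.min()
        assert len(trace) == 0

    def test_same_seed_identical_traces(self):
        cfg = small_config(max_iterations=30, seed=4)
        pop1, trace1 = ss.run_ssa(cfg, sphere, dim=4)
        pop2, trace2 = ss.run_ssa(cfg, sphere, dim=4)
        pd.testing.assert_frame_equal(trace1, trace2)
        np.testing.assert_array_equal(pop1.positions, pop2.positions)

    def test_trace_length_and_columns(self):
        cfg = small_config(max_iterations=15)
        _, trace = ss.run_ssa(cfg, sphere, dim=2)
        assert list(trace.columns) == ["iteration", "best_fitness", "mean_fitness", "winter_triggered"]
        assert len(trace) == 15

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_elitism_and_containment_random_objectives(self, seed):
        rng = np.random.default_rng(seed)
        center = rng.uniform(-4, 4, size=3)

        def objective(x):
            return float(np.sum((x - center) ** 2) + np.sin(x).sum())

        cfg = small_config(n_squirrels=12, max_iterations=40, seed=seed)
        pop, trace = ss.run_ssa(cfg, objective, dim=3)
        best = trace["best_fitness"].to_numpy()
        assert np.all(np.diff(best) <= 0)
        assert np.all(pop.positions >= -5.0) and np.all(pop.positions <= 5.0)

    def test_converges_on_quadratic(self):
        center = np.array([1.5, -2.0])
        cfg = ss.SSAConfig(
            n_squirrels=20, lower_bound=-5.0, upper_bound=5.0, max_iterations=200, seed=0
        )
        pop, _ = ss.run_ssa(cfg, lambda x: float(np.sum((x - center) ** 2)), dim=2)
        assert pop.best_fitness <= 1e-2

    def test_minimize_front_end_matches_run_ssa(self):
        cfg = small_config(max_iterations=20, seed=9)
        res = ss.SquirrelSearch(cfg).minimize(sphere, dim=3)
        pop, trace = ss.run_ssa(cfg, sphere, dim=3)
        assert res.fun == pop.best_fitness
        np.testing.assert_array_equal(res.x, pop.best_position)
        assert res.nfev == 6 + 20 * 5 + int(trace.winter_triggered.sum()) * 3


class TestRoleRefresh:
    def test_counts_and_hickory_minimality_after_refresh(self):
        cfg = small_config()
        pop = ss.initialize_population(cfg, sphere, dim=2)
        pop.fitness = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.5])
        assign_roles(pop, cfg)
        assert pop.roles[5] == "hickory"
        assert set(pop.indices_of("acorn")) == {1, 3}
        assert np.sum(pop.roles == "normal") == 3
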