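import numpy as np
import pytest

from snoreforge.selection import (FeatureMask, FitnessConfig, combine_objectives,
                                  wrapper_fitness, binarize_geo, binarize_ssa,
                                  geo_attack_vector, geo_cruise_vector,
                                  geo_coefficients, geo_step, ssa_r1,
                                  ssa_leader_update, ssa_follower_update,
                                  tent_map_sequence, stepped_inertia, sa_accept,
                                  geo_select, ssa_select, refined_ssa_select,
                                  GeoParams, SsaParams, GEOSelector, SalpSelector)


class TestObjective:
    def test_hand_evaluation(self):
        # gamma=0.25, |p|=5, N=100, alpha=0.8, beta=0.2
        assert combine_objectives(0.25, 5, 100, 0.8, 0.2) == pytest.approx(0.21)

    def test_perfect_classifier_with_no_size_penalty(self):
        assert combine_objectives(0.0, 1, 50, 0.8, 0.0) == 0.0

    def test_smaller_mask_wins_at_equal_error(self):
        full = combine_objectives(0.1, 100, 100, 0.8, 0.2)
        half = combine_objectives(0.1, 50, 100, 0.8, 0.2)
        assert half < full

    def test_wrapper_fitness_deterministic(self, planted):
        table, _ = planted
        bits = np.zeros(100, dtype=np.int8)
        bits[::10] = 1
        cfg = FitnessConfig(seed=3)
        f1 = wrapper_fitness(bits, table.X, table.labels, cfg)
        f2 = wrapper_fitness(bits, table.X, table.labels, cfg)
        assert f1 == f2

    def test_single_class_table_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            wrapper_fitness(np.ones(4, dtype=np.int8), X, np.zeros(10), FitnessConfig())

    def test_empty_mask_rejected(self, planted):
        table, _ = planted
        with pytest.raises(ValueError):
            wrapper_fitness(np.zeros(100, dtype=np.int8), table.X, table.labels,
                            FitnessConfig())


class TestBinarize:
    def test_ssa_dialect_strict_greater(self):
        np.testing.assert_array_equal(binarize_ssa(np.array([0.2, 0.7, 0.5])),
                                      [0, 1, 0])

    def test_geo_dialect_bit_set_at_or_below_theta(self):
        np.testing.assert_array_equal(binarize_geo(np.array([0.4, 0.6]), 0.5), [1, 0])

    def test_empty_ssa_mask_repaired_to_single_bit(self):
        bits = binarize_ssa(np.array([0.1, 0.4, 0.2]))
        assert bits.sum() == 1
        assert bits[1] == 1  # coordinate nearest the 0.5 threshold

    def test_geo_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            binarize_geo(np.array([0.5]), 1.5)


class TestGeoGeometry:
    def test_attack_vector_examples(self):
        np.testing.assert_array_equal(geo_attack_vector([1, 2], [0, 0]), [1, 2])
        np.testing.assert_array_equal(geo_attack_vector([3, 3], [3, 3]), [0, 0])
        with pytest.raises(ValueError):
            geo_attack_vector(np.ones(2), np.ones(3))

    def test_cruise_orthogonality_over_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d = int(rng.integers(2, 11))
            attack = rng.normal(size=d)
            w = geo_cruise_vector(attack, rng)
            assert abs(np.dot(attack, w)) < 1e-9

    def test_one_dimensional_cruise_is_zero(self):
        rng = np.random.default_rng(1)
        np.testing.assert_array_equal(geo_cruise_vector(np.array([2.0]), rng), [0.0])

    def test_zero_attack_rejected(self):
        with pytest.raises(ValueError):
            geo_cruise_vector(np.zeros(3), np.random.default_rng(0))

    def test_coefficient_schedule_endpoints_exact(self):
        cv, cw = geo_coefficients(0, 100, 0.5, 2.0, 1.0, 0.5)
        assert (cv, cw) == (0.5, 1.0)
        cv, cw = geo_coefficients(100, 100, 0.5, 2.0, 1.0, 0.5)
        assert (cv, cw) == (2.0, 0.5)

    def test_step_norm_bounded_by_coefficient_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            attack = rng.normal(size=6)
            cruise = geo_cruise_vector(attack, rng)
            step = geo_step(attack, cruise, 1.5, 0.7, rng)
            assert np.linalg.norm(step) <= 1.5 + 0.7 + 1e-12


class TestSsaPieces:
    def test_adaptive_factor_endpoints(self):
        assert ssa_r1(0, 200) == 2.0
        assert ssa_r1(200, 200) == pytest.approx(2.0 * np.exp(-16.0))

    def test_leader_stays_in_bounds(self):
        rng = np.random.default_rng(0)
        food = rng.random(20)
        for i in (0, 50, 100):
            pos = ssa_leader_update(food, ssa_r1(i, 100), 0.0, 1.0, rng)
            assert np.all((pos >= 0) & (pos <= 1))

    def test_follower_midpoint(self):
        np.testing.assert_allclose(ssa_follower_update([0, 1], [1, 0]), [0.5, 0.5])
        x = np.array([0.3, 0.9])
        np.testing.assert_allclose(ssa_follower_update(x, x), x)

    def test_follower_stays_within_input_interval(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(10), rng.random(10)
        out = ssa_follower_update(a, b)
        assert np.all(out >= np.minimum(a, b) - 1e-12)
        assert np.all(out <= np.maximum(a, b) + 1e-12)


class TestTentMap:
    def test_hand_iterates(self):
        assert tent_map_sequence(0.3, 1)[0] == pytest.approx(0.6)
        assert tent_map_sequence(0.75, 1)[0] == pytest.approx(0.5)

    def test_long_orbit_confined_to_unit_interval(self):
        seq = tent_map_sequence(0.331, 100_000)
        assert np.all((seq >= 0) & (seq < 1))

    def test_degenerate_seed_perturbed_with_warning(self):
        with pytest.warns(UserWarning):
            seq = tent_map_sequence(0.5, 10)
        assert np.all(seq < 1)


class TestInertiaAndAnnealing:
    def test_threshold_is_inclusive(self):
        assert stepped_inertia(20, 100, 0.2, 0.6, 0.8) == 0.8  # t/tmax == lambda
        assert stepped_inertia(21, 100, 0.2, 0.6, 0.8) == 0.6

    def test_final_iteration_uses_wmin(self):
        assert stepped_inertia(100, 100, 0.2, 0.6, 0.8) == 0.6

    def test_equal_weights_constant(self):
        assert stepped_inertia(5, 100, 0.2, 0.7, 0.7) == 0.7

    def test_improvement_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(sa_accept(0.1, 0.2, 1e-6, rng) for _ in range(100))

    def test_acceptance_rate_matches_boltzmann_factor(self):
        rng = np.random.default_rng(42)
        hits = sum(sa_accept(1.0, 0.0, 1.0, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(np.exp(-1.0), abs=0.02)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            sa_accept(1.0, 0.0, 0.0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def size_only_table():
    """20 noise features and a size-only objective (alpha=0)."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 20))
    y = np.array(["a", "b", "c"] * 20)
    return X, y


class TestSelectors:
    @pytest.mark.parametrize("select_fn,params,runs", [
        (geo_select, GeoParams(pop=15, iters=200), 1),
        (ssa_select, SsaParams(pop=15, iters=200), 5),
        (refined_ssa_select, SsaParams(pop=15, iters=200), 1),
    ])
    def test_size_only_objective_converges_to_single_feature(self, size_only_table,
                                                             select_fn, params, runs):
        X, y = size_only_table
        cfg = FitnessConfig(alpha=0.0, beta=1.0)
        for seed in (1, 2, 3):
            mask, trace = select_fn(X, y, cfg, params, seed=seed, runs=runs)
            assert mask.n_selected == 1
            assert np.all(np.diff(trace) <= 0)

    @pytest.mark.parametrize("select_fn,params", [
        (geo_select, GeoParams(pop=8, iters=10)),
        (ssa_select, SsaParams(pop=8, iters=10)),
        (refined_ssa_select, SsaParams(pop=8, iters=10)),
    ])
    def test_seeded_reproducibility(self, planted, select_fn, params):
        table, _ = planted
        cfg = FitnessConfig(seed=0)
        m1, t1 = select_fn(table.X, table.labels, cfg, params, seed=9)
        m2, t2 = select_fn(table.X, table.labels, cfg, params, seed=9)
        np.testing.assert_array_equal(m1.bits, m2.bits)
        assert t1 == t2

    def test_zero_iterations_returns_initialization_best(self, planted):
        table, _ = planted
        mask, trace = geo_select(table.X, table.labels, FitnessConfig(seed=0),
                                 GeoParams(pop=5, iters=0), seed=4)
        assert mask.n_selected >= 1
        assert len(trace) == 1

    def test_sklearn_selector_transforms_columns(self, planted):
        table, _ = planted
        sel = SalpSelector(refined=True, pop=8, iters=5, random_state=0)
        Xs = sel.fit(table.X, table.labels).transform(table.X)
        assert Xs.shape == (table.X.shape[0], sel.support_.sum())
        assert sel.fitness_ == sel.mask_.fitness

    def test_mask_requires_at_least_one_bit(self):
        with pytest.raises(ValueError):
            FeatureMask(bits=np.zeros(5), fitness=0.0)
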