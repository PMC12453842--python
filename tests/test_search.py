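"""Crow search: chaotic map, awareness, moves, memory discipline, and
optimizer behavior against an exhaustive oracle."""

import math

import numpy as np
import pytest

from crowfs.fitness import fitness, make_context
from crowfs.search import (ChaoticSequence, CrowState, ICSAConfig,
                           assign_neighbors, chaotic_step, dynamic_awareness,
                           global_update, initialize_population, local_update,
                           run_classic_csa, run_icsa, update_memory)
from crowfs.simulate import SyntheticSpec, generate
from crowfs.data import apply_zscore, fit_zscore

from conftest import enumerate_optimum


class TestChaoticMap:
    def test_first_two_values(self):
        seq = ChaoticSequence()
        assert chaotic_step(seq) == 0.7
        assert chaotic_step(seq) == pytest.approx(math.sin(0.7 * math.pi))
        assert math.sin(0.7 * math.pi) == pytest.approx(0.80902, abs=1e-5)

    def test_trajectory_stays_in_unit_interval(self):
        seq = ChaoticSequence()
        for _ in range(100_000):
            v = chaotic_step(seq)
            assert 0.0 <= v <= 1.0

    def test_never_hits_fixed_point_zero(self):
        c = 0.7
        for _ in range(1_000_000):
            c = math.sin(math.pi * c)
            assert c != 0.0


class TestDynamicAwareness:
    def test_ratio_one_returns_ap_max(self):
        assert dynamic_awareness(1.0, 1.0, 0.1, 0.9) == pytest.approx(0.9)

    def test_ratio_above_one_clips_to_ap_max(self):
        assert dynamic_awareness(1.5, 1.0, 0.1, 0.9) == 0.9

    def test_equal_bounds_recover_constant_awareness(self):
        assert dynamic_awareness(1.2, 0.8, 0.3, 0.3) == 0.3

    def test_nonpositive_history_rejected(self):
        with pytest.raises(ValueError):
            dynamic_awareness(1.0, 0.0, 0.1, 0.9)

    def test_always_inside_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            total = float(rng.uniform(0.01, 2))
            seen = float(rng.uniform(0.01, 2))
            v = dynamic_awareness(total, seen, 0.1, 0.9)
            assert 0.1 <= v <= 0.9


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_crows": 0}, {"max_iter": 0}, {"init_threshold": 1.5},
        {"ap_min": 0.9, "ap_max": 0.1}, {"explore_fraction": 0.0},
        {"lower_bound": 1.0, "upper_bound": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ICSAConfig(**kwargs)


class TestInitialization:
    def test_threshold_zero_selects_everything(self, oracle_problem):
        _, _, ctx = oracle_problem
        cfg = ICSAConfig(init_threshold=0.0, n_crows=3)
        crows = initialize_population(ctx, cfg, np.random.default_rng(0))
        for c in crows:
            assert c.position_mask.all()

    def test_bit_density_near_point_six(self):
        spec = SyntheticSpec(n_samples=20, n_classes=2, n_informative=1,
                             n_redundant=0, n_noise=999, effect_size=1.0,
                             seed=0)
        fm, _ = generate(spec)
        ctx = make_context(fm, np.arange(1000), cv_folds=2, seed=0)
        cfg = ICSAConfig(n_crows=10)
        crows = initialize_population(ctx, cfg, np.random.default_rng(1))
        density = np.mean([c.position_mask.mean() for c in crows])
        assert abs(density - 0.6) <= 0.05

    def test_repair_guarantees_nonempty(self, oracle_problem):
        _, _, ctx = oracle_problem
        cfg = ICSAConfig(init_threshold=1.0, n_crows=5)
        crows = initialize_population(ctx, cfg, np.random.default_rng(0))
        for c in crows:
            assert c.position_mask.sum() == 1  # repair set exactly one bit
            np.testing.assert_array_equal(c.position_mask, c.memory_mask)


class TestNeighbors:
    def test_top_crow_gets_next_six(self):
        cfg = ICSAConfig()
        nbrs = assign_neighbors(10, 0, cfg, np.random.default_rng(0))
        assert set(range(1, 7)) <= set(nbrs)
        assert 0 not in nbrs

    def test_bottom_crow_wraps(self):
        cfg = ICSAConfig()
        nbrs = assign_neighbors(10, 9, cfg, np.random.default_rng(0))
        assert set(nbrs) >= {0, 1, 2, 3, 4, 5}
        assert 9 not in nbrs

    def test_small_population_is_all_others(self):
        cfg = ICSAConfig()
        for i in range(4):
            nbrs = assign_neighbors(4, i, cfg, np.random.default_rng(0))
            assert sorted(nbrs) == sorted(set(range(4)) - {i})
            assert len(nbrs) == len(set(nbrs))

    def test_single_crow_rejected(self):
        with pytest.raises(ValueError):
            assign_neighbors(1, 0, ICSAConfig(), np.random.default_rng(0))


class TestMoves:
    def test_unit_step_lands_on_followed_memory(self):
        cfg = ICSAConfig(flight_length=2.0)
        rng = np.random.default_rng(0)
        pos = np.array([0.9, 0.1, 0.5, 0.3])
        mem = np.array([0.2, 0.8, 0.5, 0.9])
        out = local_update(pos, mem, coeff=0.5, config=cfg, rng=rng)  # c*fl=1
        np.testing.assert_allclose(out, mem)

    def test_zero_displacement_keeps_position(self):
        cfg = ICSAConfig()
        pos = np.array([0.9, 0.1, 0.5])
        out = local_update(pos, pos.copy(), coeff=0.8, config=cfg,
                           rng=np.random.default_rng(0))
        np.testing.assert_allclose(out, pos)

    def test_coordinate_arithmetic_with_clipping(self):
        cfg = ICSAConfig(flight_length=2.0)
        rng = np.random.default_rng(0)
        pos = np.array([0.0, 1.0])
        mem = np.array([1.0, 0.0])
        out = local_update(pos, mem, coeff=0.8, config=cfg, rng=rng)
        # v = 0 + 0.8*2*(1-0) = 1.6 -> clip 1 -> bit 1
        # v = 1 + 0.8*2*(0-1) = -0.6 -> clip 0 -> bit 0
        np.testing.assert_allclose(out, [1.0, 0.0])
        np.testing.assert_array_equal(out >= cfg.init_threshold,
                                      [True, False])

    def test_global_keeps_memory_outside_explored_subset(self):
        cfg = ICSAConfig(explore_fraction=0.2)
        rng = np.random.default_rng(1)
        mem = np.linspace(0, 1, 50)
        out = global_update(mem, cfg, rng)
        changed = np.flatnonzero(out != mem)
        assert len(changed) <= math.ceil(0.2 * 50)
        untouched = np.setdiff1d(np.arange(50), changed)
        np.testing.assert_array_equal(out[untouched], mem[untouched])

    def test_global_explored_density_matches_threshold(self):
        cfg = ICSAConfig(explore_fraction=0.5, init_threshold=0.4)
        rng = np.random.default_rng(0)
        mem = np.zeros(2000)
        out = global_update(mem, cfg, rng)
        explored = out != 0.0
        frac_selected = (out[explored] >= 0.4).mean()
        assert abs(frac_selected - 0.6) < 0.05

    def test_memory_update_is_strict(self, oracle_problem):
        _, _, ctx = oracle_problem
        mask = np.zeros(10)
        mask[0] = 1.0
        f = fitness(ctx, mask >= 0.4)
        crow = CrowState(position=mask.copy(), memory=mask.copy(),
                         position_fitness=f, memory_fitness=f,
                         min_fitness_seen=f.total)
        other = np.zeros(10)
        other[1] = 1.0
        same_value = fitness(ctx, mask >= 0.4)  # identical fitness
        update_memory(crow, other, same_value)
        np.testing.assert_array_equal(crow.memory, mask)  # unchanged on tie
        better = fitness(ctx, np.ones(10, bool))
        if better.total > f.total:
            update_memory(crow, np.ones(10), better)
            np.testing.assert_array_equal(crow.memory, np.ones(10))


class TestRuns:
    def test_reproducible_from_seed(self, oracle_problem):
        _, _, ctx = oracle_problem
        cfg = ICSAConfig(seed=11)
        r1 = run_icsa(ctx, cfg)
        r2 = run_icsa(ctx, cfg)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.best_fitness.total == r2.best_fitness.total
        assert r1.history == r2.history

    def test_history_length_and_monotone_best(self, oracle_problem):
        _, _, ctx = oracle_problem
        cfg = ICSAConfig(seed=2, max_iter=30)
        res = run_icsa(ctx, cfg)
        assert len(res.history["best_fitness"]) == 30
        best = res.history["best_fitness"]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert res.best_fitness.total == best[-1]

    def test_minimal_loop_single_crow(self, oracle_problem):
        _, _, ctx = oracle_problem
        cfg = ICSAConfig(seed=4, n_crows=1, max_iter=1)
        res = run_icsa(ctx, cfg)
        assert res.n_selected >= 1
        assert len(res.history["best_fitness"]) == 1

    def test_masks_always_nonempty(self, oracle_problem):
        _, _, ctx = oracle_problem
        for seed in range(3):
            res = run_icsa(ctx, ICSAConfig(seed=seed))
            assert res.n_selected >= 1
            assert res.history["best_size"][-1] >= 1

    def test_mapping_back_to_original_axis(self, oracle_problem):
        _, _, ctx = oracle_problem
        idx = np.arange(10)
        res = run_icsa(ctx, ICSAConfig(seed=0), feature_indices=idx,
                       n_original=25,
                       feature_names=[f"orig{i}" for i in range(25)])
        assert res.mask.size == 25
        assert not res.mask[10:].any()
        assert res.selected_names() == [f"orig{i}"
                                        for i in res.selected_indices]

    def test_classic_extreme_awareness_runs(self, oracle_problem):
        _, _, ctx = oracle_problem
        for ap in (0.0, 1.0):
            res = run_classic_csa(ctx, ICSAConfig(seed=0, max_iter=5),
                                  awareness=ap)
            assert res.n_selected >= 1
        with pytest.raises(ValueError):
            run_classic_csa(ctx, ICSAConfig(seed=0), awareness=1.5)

    def test_serialization_roundtrip(self, oracle_problem):
        import json
        _, _, ctx = oracle_problem
        res = run_icsa(ctx, ICSAConfig(seed=1, max_iter=3))
        payload = json.loads(res.to_json())
        assert payload["n_selected"] == res.n_selected
        assert payload["config"]["n_crows"] == 10
        assert len(payload["history"]["best_fitness"]) == 3


@pytest.fixture(scope="module")
def small_problem():
    spec = SyntheticSpec(n_samples=120, n_classes=3, n_informative=2,
                         n_redundant=0, n_noise=6, effect_size=2.0,
                         seed=5)
    fm, _ = generate(spec)
    fmz = apply_zscore(fit_zscore(fm), fm)
    ctx = make_context(fmz, np.arange(8), seed=5)
    return ctx, enumerate_optimum(ctx)


class TestOracle:
    """Exhaustive enumeration defines the exact optimum on a small problem;
    the improved search should attain it from most seeds, and the classic
    baseline should not do better on average."""

    def test_icsa_attains_enumerated_optimum(self, small_problem):
        ctx, best = small_problem
        hits = sum(
            abs(run_icsa(ctx, ICSAConfig(seed=s)).best_fitness.total
                - best.total) < 1e-12
            for s in range(5))
        assert hits >= 4

    def test_classic_not_better_on_average(self, small_problem):
        ctx, _ = small_problem
        icsa = np.mean([run_icsa(ctx, ICSAConfig(seed=s)).best_fitness.total
                        for s in range(10)])
        csa = np.mean([run_classic_csa(
            ctx, ICSAConfig(seed=s)).best_fitness.total for s in range(10)])
        assert csa <= icsa + 1e-12
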