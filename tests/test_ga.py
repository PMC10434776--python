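"""Genetic operators and the elitist single-objective loop."""

import numpy as np
import pytest

from hudopt import codec
from hudopt.errors import ConfigError
from hudopt.ga import (
    GAConfig,
    array_to_bits,
    bits_to_array,
    crossover_single_point,
    fitness_from_surrogate,
    mutate_bitflip,
    repair_onehot,
    run_ga,
    select_roulette,
)


class TestRoulette:
    def test_certain_winner(self, rng):
        idx = select_roulette(np.array([1.0, 0.0]), rng, 200)
        assert (idx == 0).all()

    def test_proportional_frequencies(self, rng):
        n = 10_000
        idx = select_roulette(np.array([3.0, 1.0]), rng, n)
        freq = (idx == 0).mean()
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) < 3 * sigma

    def test_equal_fitness_is_uniform(self, rng):
        n = 10_000
        idx = select_roulette(np.ones(4), rng, n)
        for k in range(4):
            assert abs((idx == k).mean() - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_all_zero_falls_back_to_uniform_with_warning(self, rng):
        with pytest.warns(RuntimeWarning):
            idx = select_roulette(np.zeros(3), rng, 300)
        assert set(idx) == {0, 1, 2}

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ConfigError):
            select_roulette(np.array([1.0, -0.1]), rng)


class TestVariation:
    def test_crossover_cut_mixes_suffixes(self):
        rng = np.random.default_rng(0)
        a = np.ones(26, dtype=np.uint8)
        b = np.zeros(26, dtype=np.uint8)
        c1, c2 = crossover_single_point(a, b, rng, rate=1.0)
        cut = int(np.argmax(c1 == 0)) if (c1 == 0).any() else 26
        assert 1 <= cut <= 25
        np.testing.assert_array_equal(c1[:cut], 1)
        np.testing.assert_array_equal(c1[cut:], 0)
        np.testing.assert_array_equal(c1 + c2, np.ones(26))

    def test_crossover_positional_inheritance(self, rng):
        a = rng.integers(0, 2, 26).astype(np.uint8)
        b = rng.integers(0, 2, 26).astype(np.uint8)
        c1, c2 = crossover_single_point(a, b, rng, rate=1.0)
        for i in range(26):
            assert {c1[i], c2[i]} <= {a[i], b[i]}

    def test_crossover_rate_zero_copies_parents(self, rng):
        a = rng.integers(0, 2, 26).astype(np.uint8)
        b = rng.integers(0, 2, 26).astype(np.uint8)
        c1, c2 = crossover_single_point(a, b, rng, rate=0.0)
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, b)

    def test_mutation_rate_extremes(self, rng):
        c = rng.integers(0, 2, 26).astype(np.uint8)
        np.testing.assert_array_equal(mutate_bitflip(c, 0.0, rng), c)
        np.testing.assert_array_equal(mutate_bitflip(c, 1.0, rng), 1 - c)

    def test_mutation_empirical_flip_fraction(self, rng):
        rate, trials = 0.05, 10_000
        c = np.zeros(26, dtype=np.uint8)
        flips = sum(mutate_bitflip(c, rate, rng).sum() for _ in range(trials))
        total = 26 * trials
        sigma = np.sqrt(rate * (1 - rate) / total)
        assert abs(flips / total - rate) < 3 * sigma


class TestRepair:
    def test_identity_on_valid_chromosomes(self, rng):
        for design in list(codec.iter_valid_designs())[::500]:
            arr = bits_to_array(codec.encode(design))
            np.testing.assert_array_equal(repair_onehot(arr, rng), arr)

    def test_multi_bit_group_keeps_one_set_bit_uniformly(self, rng):
        base = bits_to_array("1110" + "1000" * 3 + "10" * 5)
        counts = np.zeros(4)
        for _ in range(3000):
            fixed = repair_onehot(base, rng)
            counts[np.argmax(fixed[:4])] += 1
        assert counts[3] == 0  # bit 4 was never set
        freq = counts[:3] / 3000
        assert np.all(np.abs(freq - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 3000))

    def test_empty_group_filled_uniformly(self, rng):
        base = bits_to_array("0000" + "1000" * 3 + "10" * 5)
        counts = np.zeros(4)
        for _ in range(3000):
            counts[np.argmax(repair_onehot(base, rng)[:4])] += 1
        freq = counts / 3000
        assert np.all(np.abs(freq - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 3000))

    def test_output_always_strictly_decodable(self, rng):
        for _ in range(200):
            raw = rng.integers(0, 2, 26).astype(np.uint8)
            fixed = repair_onehot(raw, rng)
            assert codec.is_valid_chromosome(array_to_bits(fixed))


class TestFitnessTransform:
    def test_arithmetic_and_monotonicity(self):
        class Stub:
            def predict(self, X):
                return np.asarray(X)[:, 0] * 10 + 5.57

        f = fitness_from_surrogate(Stub(), upper_bound=21.0)
        pop = np.zeros((2, 26), dtype=np.uint8)
        pop[1, 0] = 1
        fit = f(pop)
        assert fit[0] == pytest.approx(21.0 - 5.57)
        assert fit[0] > fit[1]  # lower predicted load => higher fitness


def _planted_fitness(target: np.ndarray):
    """Number of groups agreeing with a hidden target design (max 9)."""
    slices = [codec.GROUP_SLICES[g.name] for g in codec.GROUPS]

    def fitness(pop: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pop))
        for s in slices:
            out += (pop[:, s] == target[s]).all(axis=1)
        return out

    return fitness


class TestRun:
    def test_planted_optimum_found_against_exhaustive_oracle(self):
        """GA matches the brute-force optimum on a planted-target fitness."""
        target = bits_to_array(codec.encode(codec.decode("00101000010010000101011001")))
        fitness = _planted_fitness(target)
        # oracle: exhaustive enumeration of all 8192 designs
        all_codes = np.stack(
            [bits_to_array(codec.encode(d)) for d in codec.iter_valid_designs()]
        )
        oracle_best = fitness(all_codes).max()
        assert oracle_best == 9.0
        hits = 0
        for seed in range(20):
            cfg = GAConfig(
                population_size=120, max_generations=60, stall_generations=60, seed=seed
            )
            hist = run_ga(fitness, cfg)
            if hist.best_fitness == oracle_best:
                hits += 1
        assert hits >= 16  # >= 80% of seeds reach the global optimum

    def test_elitism_makes_max_fitness_monotone(self):
        target = bits_to_array("10" * 13)
        cfg = GAConfig(population_size=40, max_generations=30, seed=3)
        hist = run_ga(_planted_fitness(repair_onehot(target, np.random.default_rng(0))), cfg)
        diffs = np.diff(hist.max_fitness)
        assert (diffs >= 0).all()

    def test_every_generation_strictly_decodable(self):
        seen = []

        def spy_fitness(pop):
            seen.append(pop.copy())
            return np.ones(len(pop))

        cfg = GAConfig(population_size=10, max_generations=5, stall_generations=99, seed=1)
        run_ga(spy_fitness, cfg)
        for pop in seen:
            for ind in pop:
                assert codec.is_valid_chromosome(array_to_bits(ind))

    def test_seed_determinism_and_dataset_init(self, table3):
        f = _planted_fitness(bits_to_array("1000" * 4 + "10" * 5))
        cfg = GAConfig(population_size=30, max_generations=10, init="from_dataset", seed=5)
        a = run_ga(f, cfg, dataset=table3)
        b = run_ga(f, cfg, dataset=table3)
        assert a.best_code == b.best_code
        assert a.max_fitness == b.max_fitness

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GAConfig(population_size=1).validate()
        with pytest.raises(ConfigError):
            GAConfig(crossover_rate=1.5).validate()
        with pytest.raises(ConfigError):
            run_ga(lambda p: np.ones(len(p)), GAConfig(init="from_dataset"), dataset=None)

    def test_mutation_anneal_endpoints(self):
        cfg = GAConfig(mutation_rate=0.1, mutation_rate_final=0.01, max_generations=101)
        assert cfg.mutation_rate_at(0) == pytest.approx(0.1)
        assert cfg.mutation_rate_at(100) == pytest.approx(0.01)
        fixed = GAConfig(mutation_schedule="fixed", mutation_rate=0.05)
        assert fixed.mutation_rate_at(57) == 0.05
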