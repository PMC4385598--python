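"""Genetic optimizer: encoding, operators, selection law, evolution."""

import dataclasses

import numpy as np
import pytest

from shadematch import (
    Chromosome,
    GAConfig,
    NetworkConfig,
    crossover,
    decode,
    encode,
    evolve,
    fitness,
    init_weights,
    mutate,
    roulette_select,
)
from shadematch.network import batch_errors, flatten_weights, total_mse


@pytest.mark.parametrize(
    "n,h,m,length",
    [(2, 2, 1, 9), (3, 12, 5, 113), (3, 4, 5, 41)],
)
def test_chromosome_length_counts_all_four_blocks(n, h, m, length):
    cfg = NetworkConfig(n_in=n, n_hidden=h, n_out=m)
    assert cfg.n_params == length
    assert encode(init_weights(cfg, 0)).genes.size == length


def test_encode_decode_roundtrip_exact():
    cfg = NetworkConfig(n_hidden=6)
    w = init_weights(cfg, 3)
    back = decode(encode(w), cfg)
    np.testing.assert_array_equal(flatten_weights(back), flatten_weights(w))


class TestFitness:
    def _setup(self):
        cfg = NetworkConfig(n_hidden=3)
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (10, 3))
        D = rng.uniform(0, 0.4, (10, 5))
        return cfg, X, D

    def test_monotone_decreasing_in_error(self):
        cfg, X, D = self._setup()
        gacfg = GAConfig()
        chroms = [encode(init_weights(cfg, s)) for s in range(6)]
        errors = [
            total_mse(batch_errors(decode(c, cfg), cfg, X, D)) for c in chroms
        ]
        fits = [fitness(c, X, D, cfg, gacfg) for c in chroms]
        order_by_error = np.argsort(errors)
        order_by_fitness = np.argsort(fits)[::-1]
        np.testing.assert_array_equal(order_by_error, order_by_fitness)
        assert all(f > 0 for f in fits)

    def test_trained_mode_with_zero_iterations_equals_static(self):
        cfg, X, D = self._setup()
        c = encode(init_weights(cfg, 9))
        static = fitness(c, X, D, cfg, GAConfig(fitness_mode="static_error"))
        trained0 = fitness(
            c, X, D, cfg,
            GAConfig(fitness_mode="trained_error", inner_trainer="lm_k_iters", inner_k=0),
        )
        assert static == trained0

    def test_inner_training_never_hurts_fitness(self):
        cfg, X, D = self._setup()
        c = encode(init_weights(cfg, 9))
        static = fitness(c, X, D, cfg, GAConfig())
        trained = fitness(
            c, X, D, cfg,
            GAConfig(fitness_mode="trained_error", inner_trainer="lm_k_iters", inner_k=5),
        )
        assert trained >= static


class TestRouletteSelection:
    def test_probabilities_proportional_to_fitness(self):
        pop = [Chromosome(np.array([float(i)]), fitness=f) for i, f in enumerate([3.0, 1.0])]
        rng = np.random.default_rng(123)
        n = 20_000
        picks = np.array([roulette_select(pop, rng).genes[0] for _ in range(n)])
        freq0 = np.mean(picks == 0.0)
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(freq0 - 0.75) < 4 * sigma

    def test_rejects_nonpositive_fitness(self):
        pop = [Chromosome(np.zeros(2), fitness=0.0), Chromosome(np.zeros(2), fitness=1.0)]
        with pytest.raises(ValueError):
            roulette_select(pop, np.random.default_rng(0))


class TestCrossover:
    def test_probability_zero_copies_parents(self):
        a, b = Chromosome(np.arange(5.0)), Chromosome(np.arange(5.0) + 10)
        c1, c2 = crossover(a, b, np.random.default_rng(0), GAConfig(crossover_prob=0.0))
        np.testing.assert_array_equal(c1.genes, a.genes)
        np.testing.assert_array_equal(c2.genes, b.genes)

    def test_single_cut_exchanges_tails(self):
        a = Chromosome(np.ones(4))
        b = Chromosome(np.full(4, 2.0))
        gacfg = GAConfig(crossover_prob=1.0)
        c1, c2 = crossover(a, b, np.random.default_rng(1), gacfg, cut_points=(2,))
        np.testing.assert_array_equal(c1.genes, [1, 1, 2, 2])
        np.testing.assert_array_equal(c2.genes, [2, 2, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_positionwise_sum_conserved(self, seed):
        rng = np.random.default_rng(seed)
        a = Chromosome(rng.normal(size=20))
        b = Chromosome(rng.normal(size=20))
        c1, c2 = crossover(a, b, rng, GAConfig(crossover_prob=1.0))
        np.testing.assert_allclose(c1.genes + c2.genes, a.genes + b.genes, rtol=1e-15)


class TestMutation:
    def test_probability_zero_is_identity(self):
        c = Chromosome(np.arange(10.0))
        m = mutate(c, np.random.default_rng(0), GAConfig(mutation_prob=0.0))
        np.testing.assert_array_equal(m.genes, c.genes)

    def test_probability_one_resamples_within_range(self):
        c = Chromosome(np.full(50, 99.0))
        m = mutate(c, np.random.default_rng(0),
                   GAConfig(mutation_prob=1.0, gene_range=(-1.0, 1.0)))
        assert np.all(m.genes >= -1.0) and np.all(m.genes <= 1.0)
        assert not np.any(m.genes == 99.0)

    def test_mutated_gene_count_is_binomial(self):
        """Mean mutation count over many draws matches p·L (3σ band)."""
        p_m, length, reps = 0.05, 113, 10_000
        gacfg = GAConfig(mutation_prob=p_m)
        rng = np.random.default_rng(7)
        base = Chromosome(np.full(length, 5.0))  # 5.0 outside gene_range
        counts = np.array([
            np.sum(mutate(base, rng, gacfg).genes != 5.0) for _ in range(reps)
        ])
        expected = p_m * length
        sigma_mean = np.sqrt(length * p_m * (1 - p_m) / reps)
        assert abs(counts.mean() - expected) < 3 * sigma_mean

    def test_gaussian_variant_perturbs_instead_of_resampling(self):
        c = Chromosome(np.zeros(200))
        m = mutate(c, np.random.default_rng(3),
                   GAConfig(mutation_prob=1.0, mutation_sd=0.01))
        assert np.all(np.abs(m.genes) < 0.1)
        assert np.any(m.genes != 0.0)


class TestEvolve:
    def _problem(self):
        cfg = NetworkConfig(n_hidden=3)
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (12, 3))
        D = rng.uniform(0, 0.4, (12, 5))
        return cfg, X, D

    def _gacfg(self, **kw):
        base = dict(pop_size=10, max_generations=8, seed=5)
        base.update(kw)
        return GAConfig(**base)

    def test_zero_generations_returns_best_of_initial_population(self):
        cfg, X, D = self._problem()
        gacfg = self._gacfg(max_generations=0)
        best, log = evolve(X, D, cfg, gacfg)
        assert len(log) == 1 and log[0].generation == 0
        # best decoded error must equal the best fitness in the log
        e = total_mse(batch_errors(best, cfg, X, D))
        assert 1.0 / (e + gacfg.fitness_eps) == pytest.approx(log[0].best_fitness)

    def test_elitism_makes_best_fitness_monotone(self):
        cfg, X, D = self._problem()
        _, log = evolve(X, D, cfg, self._gacfg(elitism=1))
        best = [rec.best_fitness for rec in log]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_same_seed_gives_identical_logs(self):
        cfg, X, D = self._problem()
        w1, log1 = evolve(X, D, cfg, self._gacfg())
        w2, log2 = evolve(X, D, cfg, self._gacfg())
        assert log1 == log2
        np.testing.assert_array_equal(flatten_weights(w1), flatten_weights(w2))

    def test_evolution_improves_over_random_initialization(self):
        cfg, X, D = self._problem()
        _, log = evolve(X, D, cfg, self._gacfg(max_generations=15))
        assert log[-1].best_fitness > log[0].best_fitness

    def test_target_fitness_stops_early(self):
        cfg, X, D = self._problem()
        _, log = evolve(X, D, cfg, self._gacfg(target_fitness=1e-9))
        assert len(log) == 1  # initial population already satisfies target
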