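"""Real-coded genetic algorithm for network weight initialization.

Random initial weights make small backpropagation networks land in
different local minima from run to run, which shows up as unstable
recipe predictions.  The genetic algorithm searches the initial-weight
space before gradient training starts: each individual is a flat real
chromosome holding the four network parameter blocks (input-hidden
weights, hidden-output weights, hidden thresholds, output thresholds,
in that order), its fitness is the reciprocal of the network's training
error, and the usual roulette-selection / crossover / mutation cycle
evolves the population.  The best individual ever seen is decoded into
the initial weights handed to the gradient trainer.

Fitness can optionally run a few inner training iterations (gradient
descent or Levenberg-Marquardt) before measuring the error, scoring an
individual by where training *takes* it rather than where it starts.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .network import (
    NetworkConfig,
    NetworkWeights,
    batch_errors,
    flatten_weights,
    total_mse,
    unflatten_weights,
)
from .training import LMConfig, TrainingConfig, TrainingDivergedError, train_gd, train_lm


@dataclasses.dataclass
class Chromosome:
    """A candidate initial-weight vector with its cached fitness."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness)


@dataclasses.dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``fitness_mode="static_error"`` scores the decoded network as-is;
    ``"trained_error"`` first runs the configured inner trainer for
    ``inner_k`` epochs/iterations.  ``segment_crossover=True`` restricts
    crossover cut points to the four block boundaries; the default cuts
    anywhere in the flat gene vector.  ``mutation_sd`` switches mutation
    from uniform resampling within ``gene_range`` to additive Gaussian
    perturbation of that standard deviation.
    """

    pop_size: int = 40
    max_generations: int = 50
    crossover_prob: float = 0.7
    mutation_prob: float = 0.05
    gene_range: tuple[float, float] = (-1.0, 1.0)
    fitness_mode: Literal["static_error", "trained_error"] = "static_error"
    inner_trainer: Literal["none", "gd_k_epochs", "lm_k_iters"] = "none"
    inner_k: int = 5
    fitness_eps: float = 1e-6
    elitism: int = 1
    target_fitness: float | None = None
    seed: int = 0
    segment_crossover: bool = False
    mutation_sd: float | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.gene_range[0] >= self.gene_range[1]:
            raise ValueError("gene_range must be (lo, hi) with lo < hi")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")
        if self.fitness_eps <= 0:
            raise ValueError("fitness_eps must be positive")


def encode(w: NetworkWeights) -> Chromosome:
    """Flatten the four parameter blocks into a chromosome."""
    return Chromosome(flatten_weights(w))


def decode(c: Chromosome, cfg: NetworkConfig) -> NetworkWeights:
    """Rebuild network weights from a chromosome (inverse of encode)."""
    return unflatten_weights(c.genes, cfg)


def segment_boundaries(cfg: NetworkConfig) -> tuple[int, int, int]:
    """Interior cut points between the four chromosome segments."""
    a = cfg.n_in * cfg.n_hidden
    b = a + cfg.n_hidden * cfg.n_out
    return a, b, b + cfg.n_hidden


def fitness(
    c: Chromosome,
    X: np.ndarray,
    D: np.ndarray,
    cfg: NetworkConfig,
    gacfg: GAConfig,
    tcfg: TrainingConfig | None = None,
) -> float:
    """Score a chromosome as 1 / (E + ε).

    E is the network's error on the (normalized) training batch — the
    mean of squared per-sample errors — measured either on the decoded
    weights directly or after the configured inner training.  Strictly
    positive and strictly decreasing in E; a non-finite E scores the
    floor value ε so that roulette selection stays well defined.
    """
    w = decode(c, cfg)
    try:
        if gacfg.fitness_mode == "trained_error" and gacfg.inner_k > 0:
            if gacfg.inner_trainer == "gd_k_epochs":
                inner = dataclasses.replace(
                    tcfg or TrainingConfig(), max_epochs=gacfg.inner_k, goal_error=0.0
                )
                w, _ = train_gd(X, D, cfg, inner, init=w)
            elif gacfg.inner_trainer == "lm_k_iters":
                w, _ = train_lm(X, D, cfg, w, LMConfig(max_iter=gacfg.inner_k))
        errs = batch_errors(w, cfg, X, D)
        e = total_mse(errs, as_printed=True)
    except (TrainingDivergedError, FloatingPointError):
        return gacfg.fitness_eps
    if not np.isfinite(e):
        return gacfg.fitness_eps
    return 1.0 / (e + gacfg.fitness_eps)


def roulette_select(population: list[Chromosome], rng: np.random.Generator) -> Chromosome:
    """Fitness-proportional selection: p_i = f_i / Σ f_j."""
    f = np.array([c.fitness for c in population], dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("roulette selection requires positive finite fitnesses")
    total = f.sum()
    idx = rng.choice(len(population), p=f / total)
    return population[idx]


def crossover(
    a: Chromosome,
    b: Chromosome,
    rng: np.random.Generator,
    gacfg: GAConfig,
    cut_points: tuple[int, ...] | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover exchanging the tails of two parents.

    With probability ``crossover_prob`` a cut point is drawn and the
    gene ranges beyond it are swapped; otherwise the children are plain
    copies.  Every child position carries the gene of exactly one
    parent, so positionwise sums are conserved.  ``cut_points``
    restricts the admissible cuts (used for segment-aligned crossover);
    by default any interior position is admissible.
    """
    if a.genes.shape != b.genes.shape:
        raise ValueError("parents must have equal gene counts")
    g1, g2 = a.genes.copy(), b.genes.copy()
    if rng.random() < gacfg.crossover_prob and g1.size > 1:
        if cut_points:
            valid = [c for c in cut_points if 0 < c < g1.size]
            cut = int(rng.choice(valid)) if valid else 1
        else:
            cut = int(rng.integers(1, g1.size))
        g1[cut:], g2[cut:] = b.genes[cut:].copy(), a.genes[cut:].copy()
    return Chromosome(g1), Chromosome(g2)


def mutate(c: Chromosome, rng: np.random.Generator, gacfg: GAConfig) -> Chromosome:
    """Mutate each gene independently with probability ``mutation_prob``.

    Default is uniform resampling within ``gene_range``; with
    ``mutation_sd`` set, a Gaussian perturbation is added instead.
    """
    genes = c.genes.copy()
    mask = rng.random(genes.size) < gacfg.mutation_prob
    k = int(mask.sum())
    if k:
        if gacfg.mutation_sd is None:
            lo, hi = gacfg.gene_range
            genes[mask] = rng.uniform(lo, hi, k)
        else:
            genes[mask] += rng.normal(0.0, gacfg.mutation_sd, k)
    return Chromosome(genes)


@dataclasses.dataclass(frozen=True)
class GenerationLog:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_error: float


def evolve(
    X: np.ndarray,
    D: np.ndarray,
    cfg: NetworkConfig,
    gacfg: GAConfig,
    tcfg: TrainingConfig | None = None,
) -> tuple[NetworkWeights, list[GenerationLog]]:
    """Run the full GA and return the best initial weights found.

    Initializes ``pop_size`` chromosomes uniformly within
    ``gene_range``, then iterates roulette selection, crossover and
    mutation, carrying the ``elitism`` best individuals over unchanged.
    Stops at ``max_generations`` (0 returns the best of the random
    initial population) or when ``target_fitness`` is reached.  The log
    records best/mean fitness and the best network error per
    generation, including generation 0.  Fully deterministic given
    ``gacfg.seed``.
    """
    cut_points = segment_boundaries(cfg) if gacfg.segment_crossover else None
    rng = np.random.default_rng(gacfg.seed)
    lo, hi = gacfg.gene_range
    population = [
        Chromosome(rng.uniform(lo, hi, cfg.n_params)) for _ in range(gacfg.pop_size)
    ]

    def score(pop: list[Chromosome]) -> None:
        for c in pop:
            if c.fitness is None:
                c.fitness = fitness(c, X, D, cfg, gacfg, tcfg)

    score(population)
    best_ever = max(population, key=lambda c: c.fitness).copy()
    log: list[GenerationLog] = []

    def record(gen: int) -> None:
        fits = np.array([c.fitness for c in population])
        log.append(
            GenerationLog(
                generation=gen,
                best_fitness=float(fits.max()),
                mean_fitness=float(fits.mean()),
                best_error=1.0 / best_ever.fitness - gacfg.fitness_eps,
            )
        )

    record(0)
    for gen in range(1, gacfg.max_generations + 1):
        if gacfg.target_fitness is not None and best_ever.fitness >= gacfg.target_fitness:
            break
        elite = sorted(population, key=lambda c: c.fitness, reverse=True)
        next_pop = [elite[i].copy() for i in range(min(gacfg.elitism, len(elite)))]
        while len(next_pop) < gacfg.pop_size:
            p1 = roulette_select(population, rng)
            p2 = roulette_select(population, rng)
            c1, c2 = crossover(p1, p2, rng, gacfg, cut_points=cut_points)
            next_pop.append(mutate(c1, rng, gacfg))
            if len(next_pop) < gacfg.pop_size:
                next_pop.append(mutate(c2, rng, gacfg))
        population = next_pop
        score(population)
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best_ever.fitness:
            best_ever = gen_best.copy()
        record(gen)

    return decode(best_ever, cfg), log
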