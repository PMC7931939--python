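"""Genetic-algorithm search over the discrete neural hyperparameter grids.

Chromosomes index into the enumerated grids (hidden layers x neurons x
batch size x epochs = 4 x 5 x 4 x 7 = 560 points), so every individual the
operators emit decodes to a legal architecture.  The GA uses tournament
selection (size 3), single-point crossover at rate 0.80, per-gene mutation
at rate 0.20, elitism of one, and the stopping rule: run at least
``min_generations`` (default 100), then stop at the first window of
``stall_window`` (default 20) consecutive generations without improvement
of the best objective.  Fitness values are cached so each unique chromosome
is evaluated once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forecasters import (
    BATCH_SIZE_GRID,
    EPOCHS_GRID,
    HIDDEN_LAYERS_GRID,
    NEURONS_GRID,
    NeuralSpec,
)

__all__ = ["DEFAULT_SPACE", "Chromosome", "GAConfig", "GAResult",
           "decode", "mutate", "crossover", "ga_search"]

# One grid per gene, in chromosome order.
DEFAULT_SPACE: tuple[tuple, ...] = (
    HIDDEN_LAYERS_GRID,
    NEURONS_GRID,
    BATCH_SIZE_GRID,
    EPOCHS_GRID,
)

Chromosome = tuple[int, ...]  # gene k is an index into space[k]


@dataclass(frozen=True)
class GAConfig:
    mutation_rate: float = 0.20
    crossover_rate: float = 0.80
    population_size: int = 20
    min_generations: int = 100
    stall_window: int = 20
    elitism: int = 1
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.stall_window > self.min_generations:
            raise ValueError("stall_window must not exceed min_generations")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass(frozen=True)
class GAResult:
    best: Chromosome
    best_objective: float
    generations: int
    evaluations: int
    history: tuple[float, ...] = field(repr=False, default=())


def decode(chromosome: Chromosome, space=DEFAULT_SPACE, **spec_kwargs) -> NeuralSpec:
    """Decode a chromosome over the default space into a NeuralSpec."""
    layers, neurons, batch, epochs = (grid[g] for g, grid in zip(chromosome, space))
    return NeuralSpec(hidden_layers=layers, neurons_per_layer=neurons,
                      batch_size=batch, epochs=epochs, **spec_kwargs)


def _random_chromosome(space, rng) -> Chromosome:
    return tuple(int(rng.integers(len(grid))) for grid in space)


def mutate(chromosome: Chromosome, rate: float, rng: np.random.Generator,
           space=DEFAULT_SPACE) -> Chromosome:
    """Resample each gene independently with probability ``rate``."""
    return tuple(
        int(rng.integers(len(grid))) if rng.random() < rate else gene
        for gene, grid in zip(chromosome, space)
    )


def crossover(parent_a: Chromosome, parent_b: Chromosome, rate: float,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover with probability ``rate``, else copy parents."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    if rng.random() >= rate or len(parent_a) < 2:
        return parent_a, parent_b
    point = int(rng.integers(1, len(parent_a)))
    return (parent_a[:point] + parent_b[point:], parent_b[:point] + parent_a[point:])


def ga_search(fitness, config: GAConfig = GAConfig(), space=DEFAULT_SPACE) -> GAResult:
    """Minimize ``fitness(chromosome)`` over the discrete space.

    Returns the best-ever chromosome.  The best objective is non-increasing
    across generations (elitism) and the search trajectory is a pure
    function of ``config.seed``.
    """
    if not space or any(len(grid) == 0 for grid in space):
        raise ValueError("search space must be nonempty")
    rng = np.random.default_rng(config.seed)
    cache: dict[Chromosome, float] = {}

    def evaluate(ch: Chromosome) -> float:
        if ch not in cache:
            cache[ch] = float(fitness(ch))
        return cache[ch]

    population = [_random_chromosome(space, rng) for _ in range(config.population_size)]
    scores = [evaluate(ch) for ch in population]
    best_idx = int(np.argmin(scores))
    best, best_obj = population[best_idx], scores[best_idx]

    history = [best_obj]
    generation = 0
    stall = 0
    while generation < config.min_generations or stall < config.stall_window:
        generation += 1
        order = np.argsort(scores)
        elite = [population[i] for i in order[: config.elitism]]
        children: list[Chromosome] = list(elite)
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(config.population_size, size=config.tournament_size)
                winner = min(contenders, key=lambda i: scores[i])
                parents.append(population[winner])
            child_a, child_b = crossover(parents[0], parents[1], config.crossover_rate, rng)
            children.append(mutate(child_a, config.mutation_rate, rng, space))
            if len(children) < config.population_size:
                children.append(mutate(child_b, config.mutation_rate, rng, space))
        population = children
        scores = [evaluate(ch) for ch in population]
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_obj:
            best, best_obj = population[gen_best], scores[gen_best]
            stall = 0
        else:
            stall += 1
        history.append(best_obj)
    return GAResult(best, best_obj, generation, len(cache), tuple(history))
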