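"""Real-coded genetic algorithm over BP connection weights (GA-BP).

The GA searches the network's weight space before gradient descent starts:
each individual is the full weight set flattened into a real vector, scored
by fitness f = 1 / (E + eps) where E is the network's global error on the
training set. Selection is roulette-wheel on normalized fitness with one
elitist survivor; variation is arithmetic crossover and sparse Gaussian
mutation. The best genome ever seen seeds ordinary BP training
(``ga_bp_train``), so the comparison against a random start isolates the
effect of initialization.

Crossover/mutation rates are fixed by default (0.3 / 0.01); the adaptive
scheme P_c = c*(f_max - f_a), P_m = d*(f_max - f_a) on the population's
max-minus-mean fitness spread can be enabled, clamped to a safe range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bp import NetworkConfig, NetworkWeights, TrainResult, _as_xy, global_error, train

#: Guard added to E in the fitness so a perfect individual (E = 0) has a
#: large finite fitness instead of dividing by zero.
FITNESS_EPS = 1e-12


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary control parameters.

    Defaults follow the evaluation protocol: 40 generations of a
    20-individual population with fixed crossover probability 0.3 and
    mutation probability 0.01, one elitist survivor. ``adaptive=True``
    switches the rates to c/d times the population fitness spread, clamped
    into [rate_floor, rate_ceiling].
    """

    population_size: int = 20
    n_generations: int = 40
    crossover_prob: float = 0.3
    mutation_prob: float = 0.01
    adaptive: bool = False
    adaptive_c: float = 0.5
    adaptive_d: float = 0.05
    elitism_count: int = 1
    rate_floor: float = 0.01
    rate_ceiling: float = 0.99
    mutation_sigma: float = 0.1
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not (0.0 < self.crossover_prob <= 1.0):
            raise ValueError("crossover_prob must be in (0, 1]")
        if not (0.0 < self.mutation_prob < 1.0):
            raise ValueError("mutation_prob must be in (0, 1)")
        if self.adaptive_c >= 1 or self.adaptive_d >= 1:
            raise ValueError("adaptive constants c, d must be < 1")
        if self.elitism_count < 0:
            raise ValueError("elitism_count must be >= 0")
        if not (0.0 <= self.rate_floor <= self.rate_ceiling):
            raise ValueError("require 0 <= rate_floor <= rate_ceiling")


@dataclass
class Individual:
    """A real-coded genome with its training error and fitness."""

    genome: np.ndarray
    error: float
    fitness: float


@dataclass
class EvolutionTrace:
    """Per-generation summary of the population (one entry per generation)."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    max_fitness: list[float] = field(default_factory=list)
    best_error: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self.best_fitness) + 1),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "max_fitness": self.max_fitness,
                "best_error": self.best_error,
            }
        )


def genome_length(config: NetworkConfig) -> int:
    """Number of real genes: (m+1)*H input weights plus (H+1)*l output weights."""
    return (config.n_input + 1) * config.hidden + (config.hidden + 1) * config.n_output


def encode(weights: NetworkWeights) -> np.ndarray:
    """Flatten weights into a genome: V (row-major) then W (row-major)."""
    return np.concatenate([weights.V.ravel(), weights.W.ravel()])


def decode(genome: np.ndarray, config: NetworkConfig) -> NetworkWeights:
    """Inverse of :func:`encode` for the architecture in ``config``."""
    genome = np.asarray(genome, dtype=float)
    expected = genome_length(config)
    if genome.shape != (expected,):
        raise ValueError(f"genome length {genome.shape} != expected ({expected},)")
    n_v = (config.n_input + 1) * config.hidden
    V = genome[:n_v].reshape(config.n_input + 1, config.hidden)
    W = genome[n_v:].reshape(config.hidden + 1, config.n_output)
    return NetworkWeights(V, W)


def fitness_of(error: float) -> float:
    """Fitness f = 1 / (E + eps); strictly decreasing in the error E >= 0."""
    if error < 0:
        raise ValueError(f"error must be >= 0, got {error}")
    return 1.0 / (error + FITNESS_EPS)


def selection_probs(fitnesses: np.ndarray) -> np.ndarray:
    """Roulette probabilities P_i = f_i / sum(f); requires all f_i > 0."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size == 0:
        raise ValueError("fitness vector must be non-empty")
    if np.any(fitnesses <= 0):
        raise ValueError("all fitnesses must be > 0")
    return fitnesses / fitnesses.sum()


def roulette_select(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one population index with probability proportional to fitness."""
    probs = np.asarray(probs, dtype=float)
    return int(rng.choice(probs.size, p=probs))


def crossover(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-arithmetic crossover: children are complementary convex mixes.

    With alpha ~ U(0,1): child1 = alpha*p1 + (1-alpha)*p2 and child2 the
    mirror mix, so every child gene lies between the parents' genes.
    """
    parent1 = np.asarray(parent1, dtype=float)
    parent2 = np.asarray(parent2, dtype=float)
    if parent1.shape != parent2.shape:
        raise ValueError("parents must have equal genome lengths")
    alpha = rng.uniform()
    child1 = alpha * parent1 + (1.0 - alpha) * parent2
    child2 = (1.0 - alpha) * parent1 + alpha * parent2
    return child1, child2


def mutate(
    genome: np.ndarray,
    mutation_prob: float,
    rng: np.random.Generator,
    sigma: float = 0.1,
) -> np.ndarray:
    """Perturb each gene independently with probability P_m by N(0, sigma) noise."""
    if not (0.0 <= mutation_prob <= 1.0):
        raise ValueError("mutation_prob must be in [0, 1]")
    genome = np.asarray(genome, dtype=float).copy()
    mask = rng.uniform(size=genome.shape) < mutation_prob
    if mask.any():
        genome[mask] += rng.normal(0.0, sigma, size=int(mask.sum()))
    return genome


def adaptive_rates(
    f_max: float,
    f_mean: float,
    c: float,
    d: float,
    rate_floor: float = 0.01,
    rate_ceiling: float = 0.99,
) -> tuple[float, float]:
    """Adaptive P_c = c*(f_max - f_mean), P_m = d*(f_max - f_mean), clamped.

    A converged population (zero spread) drives both rates to the floor,
    keeping some variation alive; a spread-out population raises them.
    """
    if f_max < f_mean:
        raise ValueError("f_max must be >= mean fitness")
    spread = f_max - f_mean
    pc = min(max(c * spread, rate_floor), rate_ceiling)
    pm = min(max(d * spread, rate_floor), rate_ceiling)
    return pc, pm


def evolve_genomes(
    ga_config: GAConfig,
    error_fn,
    length: int,
    initial_population: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, EvolutionTrace]:
    """Run the GA on real genomes of a given length; return (best ever, trace).

    ``error_fn(genome) -> E >= 0`` defines the objective; fitness is
    1/(E+eps). Each generation: score everyone, copy the elite unchanged,
    fill the rest by roulette selection + crossover (with probability P_c)
    + mutation. Deterministic given the GA seed.
    """
    rng = np.random.default_rng(ga_config.seed)
    if initial_population is None:
        population = rng.uniform(
            -ga_config.init_scale, ga_config.init_scale,
            size=(ga_config.population_size, length),
        )
    else:
        population = np.array(initial_population, dtype=float)
        if population.shape != (ga_config.population_size, length):
            raise ValueError(
                f"initial population shape {population.shape} != "
                f"({ga_config.population_size}, {length})"
            )

    trace = EvolutionTrace()
    best_genome: Optional[np.ndarray] = None
    best_error = np.inf

    def score(pop: np.ndarray) -> np.ndarray:
        return np.array([error_fn(g) for g in pop])

    for _ in range(ga_config.n_generations):
        errors = score(population)
        fitnesses = np.array([fitness_of(e) for e in errors])
        order = np.argsort(errors)  # ascending error = descending fitness
        if errors[order[0]] < best_error:
            best_error = float(errors[order[0]])
            best_genome = population[order[0]].copy()
        trace.best_fitness.append(fitness_of(best_error))
        trace.mean_fitness.append(float(fitnesses.mean()))
        trace.max_fitness.append(float(fitnesses.max()))
        trace.best_error.append(best_error)

        if ga_config.adaptive:
            pc, pm = adaptive_rates(
                float(fitnesses.max()), float(fitnesses.mean()),
                ga_config.adaptive_c, ga_config.adaptive_d,
                ga_config.rate_floor, ga_config.rate_ceiling,
            )
        else:
            pc, pm = ga_config.crossover_prob, ga_config.mutation_prob

        probs = selection_probs(fitnesses)
        next_pop: list[np.ndarray] = [
            population[order[k]].copy()
            for k in range(min(ga_config.elitism_count, ga_config.population_size))
        ]
        while len(next_pop) < ga_config.population_size:
            p1 = population[roulette_select(probs, rng)]
            p2 = population[roulette_select(probs, rng)]
            if rng.uniform() < pc:
                c1, c2 = crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if len(next_pop) < ga_config.population_size:
                    next_pop.append(
                        mutate(child, pm, rng, sigma=ga_config.mutation_sigma)
                    )
        population = np.array(next_pop)

    if best_genome is None:
        # zero generations requested: fall back to the best of the initial pool
        errors = score(population)
        k = int(np.argmin(errors))
        best_genome, best_error = population[k].copy(), float(errors[k])
        trace.best_fitness.append(fitness_of(best_error))
        trace.mean_fitness.append(float(np.mean([fitness_of(e) for e in errors])))
        trace.max_fitness.append(trace.best_fitness[-1])
        trace.best_error.append(best_error)
    return best_genome, trace


def evolve(
    ga_config: GAConfig,
    net_config: NetworkConfig,
    dataset,
    initial_population: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, EvolutionTrace]:
    """GA search over the network's weight space; returns (best genome, trace).

    Individuals are flattened weight sets (:func:`encode` layout), scored by
    the network's global error on the training set.
    """
    X, B = _as_xy(dataset)

    def error_fn(genome: np.ndarray) -> float:
        return global_error(decode(genome, net_config), (X, B))

    return evolve_genomes(
        ga_config, error_fn, genome_length(net_config), initial_population
    )


def ga_bp_train(
    ga_config: GAConfig, net_config: NetworkConfig, dataset
) -> tuple[TrainResult, EvolutionTrace]:
    """GA weight search followed by BP refinement (the full GA-BP procedure).

    The best genome found by :func:`evolve` is decoded into initial weights
    and handed to :func:`melasma_gabp.bp.train`; the returned TrainResult is
    flagged ``ga_initialized``.
    """
    best_genome, trace = evolve(ga_config, net_config, dataset)
    initial = decode(best_genome, net_config)
    result = train(net_config, dataset, initial_weights=initial)
    result.ga_initialized = True
    return result, trace
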