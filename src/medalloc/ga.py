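"""Generic seeded genetic-algorithm maximizer (binary and permutation encodings).

Selection is rank-proportional (robust to fitness scaling), crossover is
single-point for bit strings and order crossover (OX) for tours, and a
mutation event changes exactly one gene: a single bit flip, or a single
swap of two tour positions. Elites are copied unchanged into the next
generation, so the best-fitness history is monotone. All randomness flows
through one numpy Generator created from the config seed; identical
configs produce bitwise-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GAConfig",
    "GAResult",
    "ga_maximize",
    "single_point_crossover",
    "order_crossover",
    "mutate",
    "select_parents",
]

Encoding = Literal["binary", "permutation"]


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary hyperparameters.

    Defaults follow the allocation use: population 1000, mutation
    probability 0.5 (per offspring), patience 250 generations without
    improvement, cap 1000 generations. ``elitism_count`` defaults to 5%
    of the population (at least 1), which keeps the fitness history
    monotone.
    """

    encoding: Encoding = "binary"
    population_size: int = 1000
    mutation_prob: float = 0.5
    crossover_prob: float = 0.8
    max_iterations: int = 1000
    patience: int = 250
    seed: int = 0
    elitism_count: int | None = None

    def __post_init__(self) -> None:
        if self.encoding not in ("binary", "permutation"):
            raise ValueError(f"unknown encoding: {self.encoding!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.patience > self.max_iterations:
            raise ValueError("patience must be <= max_iterations")
        if self.effective_elitism >= self.population_size:
            raise ValueError("elitism_count must be < population_size")

    @property
    def effective_elitism(self) -> int:
        if self.elitism_count is not None:
            return self.elitism_count
        return max(1, math.ceil(0.05 * self.population_size))


@dataclass(frozen=True)
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness in the population, per generation
    generations_run: int
    stop_reason: Literal["patience", "max_iterations"]


def single_point_crossover(p1, p2, point=None, rng=None):
    """Swap suffixes of two equal-length bit vectors at ``point``.

    ``point`` in [1, length) is drawn from ``rng`` when omitted. The
    multiset of bits at every locus is preserved across the pair.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError(f"length mismatch: {p1.shape} vs {p2.shape}")
    n = p1.size
    if point is None:
        point = int(rng.integers(1, n)) if n > 1 else 1
    if not 1 <= point < max(n, 2):
        raise ValueError(f"crossover point must be in [1, {n}), got {point}")
    c1 = np.concatenate([p1[:point], p2[point:]])
    c2 = np.concatenate([p2[:point], p1[point:]])
    return c1, c2


def order_crossover(p1, p2, i=None, j=None, rng=None):
    """Order crossover (OX) of two permutations of the same element set.

    The child inherits ``p1[i..j]`` in place; the remaining positions are
    filled left-to-right with the elements missing from that slice, in the
    order they appear in ``p2``. Always yields a valid permutation.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape or set(p1.tolist()) != set(p2.tolist()):
        raise ValueError("parents must be permutations of the same element set")
    n = p1.size
    if i is None or j is None:
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
    if not 0 <= i < j < n:
        raise ValueError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    child = np.empty_like(p1)
    child[i : j + 1] = p1[i : j + 1]
    kept = set(p1[i : j + 1].tolist())
    fill = [x for x in p2.tolist() if x not in kept]
    positions = [k for k in range(n) if not i <= k <= j]
    child[positions] = fill
    return child


def mutate(chromosome, encoding: Encoding, mutation_prob: float, rng):
    """One-gene mutation with probability ``mutation_prob`` per call.

    Binary: flip one uniformly chosen bit. Permutation: swap two uniformly
    chosen distinct positions (output remains a permutation). Otherwise the
    chromosome is returned unchanged (a copy is always made).
    """
    child = np.array(chromosome, copy=True)
    if rng.random() >= mutation_prob:
        return child
    n = child.size
    if encoding == "binary":
        locus = int(rng.integers(n))
        child[locus] = 1 - child[locus]
    else:
        if n >= 2:
            a, b = rng.choice(n, size=2, replace=False)
            child[a], child[b] = child[b], child[a]
    return child


def _rank_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    # Selection probability proportional to 1-based fitness rank; average
    # ranks on ties, so an all-equal population is sampled uniformly.
    ranks = rankdata(fitnesses, method="average")
    return ranks / ranks.sum()


def select_parents(population, fitnesses, rng):
    """Draw a parent pair by rank-proportional selection (with replacement)."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("fitnesses must be finite")
    probs = _rank_probabilities(fitnesses)
    i, j = rng.choice(len(population), size=2, replace=True, p=probs)
    return population[i], population[j]


def _initial_population(length: int, config: GAConfig, rng) -> list[np.ndarray]:
    if config.encoding == "binary":
        return [rng.integers(0, 2, size=length) for _ in range(config.population_size)]
    return [rng.permutation(length) for _ in range(config.population_size)]


def _evaluate(fitness_fn, chromosome) -> float:
    value = float(fitness_fn(chromosome))
    if not np.isfinite(value):
        raise ValueError(
            f"fitness function returned non-finite value {value!r} "
            f"for chromosome {np.asarray(chromosome).tolist()}"
        )
    return value


def ga_maximize(
    fitness_fn: Callable[[np.ndarray], float], length: int, config: GAConfig
) -> GAResult:
    """Maximize ``fitness_fn`` over chromosomes of the given length.

    Each generation: rank selection -> crossover (with probability
    ``crossover_prob``, else cloned parents) -> one-gene mutation (with
    probability ``mutation_prob`` per offspring) -> elitist replacement.
    Stops after ``patience`` generations without best-fitness improvement,
    or at ``max_iterations``.
    """
    if length < 1:
        raise ValueError("chromosome length must be >= 1")
    rng = np.random.default_rng(config.seed)
    population = _initial_population(length, config, rng)
    fitnesses = np.array([_evaluate(fitness_fn, c) for c in population])

    n_elite = config.effective_elitism
    n_offspring = config.population_size - n_elite
    history = [float(fitnesses.max())]
    best_idx = int(np.argmax(fitnesses))
    best_chromosome = population[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])
    stall = 0
    stop_reason = "max_iterations"
    generation = 0

    for generation in range(1, config.max_iterations + 1):
        order = np.argsort(fitnesses)[::-1]
        elites = [population[k].copy() for k in order[:n_elite]]
        elite_fit = fitnesses[order[:n_elite]]

        probs = _rank_probabilities(fitnesses)
        parent_idx = rng.choice(
            config.population_size, size=(n_offspring, 2), replace=True, p=probs
        )
        offspring = []
        k = 0
        while len(offspring) < n_offspring:
            ia, ib = parent_idx[k]
            k += 1
            pa, pb = population[ia], population[ib]
            if rng.random() < config.crossover_prob:
                if config.encoding == "binary":
                    c1, c2 = single_point_crossover(pa, pb, rng=rng)
                else:
                    c1 = order_crossover(pa, pb, rng=rng)
                    c2 = order_crossover(pb, pa, rng=rng)
            else:
                c1, c2 = pa.copy(), pb.copy()
            for child in (c1, c2):
                if len(offspring) < n_offspring:
                    offspring.append(
                        mutate(child, config.encoding, config.mutation_prob, rng)
                    )
        offspring_fit = np.array([_evaluate(fitness_fn, c) for c in offspring])

        population = elites + offspring
        fitnesses = np.concatenate([elite_fit, offspring_fit])
        gen_best = int(np.argmax(fitnesses))
        history.append(float(fitnesses[gen_best]))
        if fitnesses[gen_best] > best_fitness:
            best_fitness = float(fitnesses[gen_best])
            best_chromosome = population[gen_best].copy()
            stall = 0
        else:
            stall += 1
        if stall >= config.patience:
            stop_reason = "patience"
            break

    return GAResult(
        best_chromosome=best_chromosome,
        best_fitness=best_fitness,
        history=np.asarray(history),
        generations_run=generation,
        stop_reason=stop_reason,
    )
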