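"""Real-coded genetic algorithm with roulette selection, BLX-μ crossover
and nonuniform mutation.

The algorithm minimizes a nonnegative objective (here: the mean squared
error of the network a chromosome encodes).  Chromosomes are real gene
vectors constrained to ``[lower_bound, upper_bound]``.

Operators
---------
*Roulette-wheel selection* draws individuals with probability proportional
to a selection weight.  Because the objective is minimized, raw fitness is
transformed to ``s_i = 1 / (f_i + ε)`` before spinning the wheel.

*BLX-μ crossover* blends two parent genes ``v1 ≤ v2`` by sampling the
offspring uniformly on the extended interval ``[v1 − μ(v2−v1), v2 + μ(v2−v1)]``,
resampling when the draw leaves the gene bounds (capped, then clamped).
μ = 0.5 is the default, the value reported to work best.

*Nonuniform mutation* moves a gene toward one bound (fair coin λ) by
``Δ(n, y) = y · (1 − β^{(1−n/N)^q})`` with β uniform on [0, 1]: steps span
the whole range early in the run and anneal toward zero as the generation
index n approaches the horizon N.  The random draws are ordered λ then β
so that seeded runs are reproducible.

The generational loop applies selection → crossover → mutation → greedy
survivor competition (an offspring replaces its first parent only if it is
not worse), with single-chromosome elitism so the best-ever fitness trace
is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROULETTE_EPS = 1e-12


@dataclass
class Chromosome:
    """Real gene vector with its (lower-is-better) MSE fitness."""

    genes: np.ndarray
    fitness: float = np.inf

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness)


@dataclass
class RCGAConfig:
    """Run parameters; defaults follow the reported algorithm settings."""

    population_size: int = 30
    generations: int = 100
    crossover_prob: float = 0.1
    mutation_prob: float = 0.01
    blx_mu: float = 0.5
    mutation_q: float = 2.0
    lower_bound: float = -5.0
    upper_bound: float = 5.0
    seed: int | None = None
    target_fitness: float | None = None
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.blx_mu < 0:
            raise ValueError("blx_mu must be >= 0")
        if self.mutation_q <= 0:
            raise ValueError("mutation_q must be > 0")


def selection_weights(fitnesses: np.ndarray, eps: float = ROULETTE_EPS) -> np.ndarray:
    """Minimization transform: weight 1/(fitness + ε), so low MSE wins slots."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one individual")
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("fitnesses must be finite and nonnegative")
    return 1.0 / (f + eps)


def roulette_spin(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Spin a wheel whose slot widths are the given nonnegative weights.

    All-zero weights degenerate to a uniform draw (documented fallback).
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return int(rng.integers(w.size))
    return int(np.searchsorted(np.cumsum(w), rng.uniform(0, total), side="right")
               .clip(0, w.size - 1))


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Select one index with probability proportional to 1/(fitness + ε)."""
    return roulette_spin(selection_weights(fitnesses), rng)


def blx_crossover(v1: float, v2: float, mu: float,
                  lower: float, upper: float, rng: np.random.Generator,
                  c: float | None = None, max_resamples: int = 100) -> float:
    """One BLX-μ offspring gene from parent genes v1, v2.

    With ``c`` given, the blend coefficient is fixed (deterministic form
    ``p = α₁ + c (α₂ − α₁)``); otherwise c is drawn uniformly, resampling
    up to ``max_resamples`` times while p leaves [lower, upper], after
    which p is clamped to the violated bound.
    """
    if not (np.isfinite(v1) and np.isfinite(v2)):
        raise ValueError("parent genes must be finite")
    lo, hi = (v1, v2) if v1 <= v2 else (v2, v1)
    span = hi - lo
    a1 = lo - mu * span
    a2 = hi + mu * span
    if c is not None:
        return a1 + c * (a2 - a1)
    for _ in range(max_resamples):
        p = a1 + rng.uniform() * (a2 - a1)
        if lower <= p <= upper:
            return p
    return float(np.clip(p, lower, upper))


def nonuniform_mutate(y: float, n: int, N: int, q: float,
                      lower: float, upper: float, rng: np.random.Generator,
                      lam: int | None = None, beta: float | None = None) -> float:
    """Nonuniform mutation of one gene at generation n of N.

    λ = 0 moves toward the upper bound by Δ(n, upper − y); λ = 1 toward the
    lower bound by Δ(n, y − lower).  Δ(n, y) ∈ [0, y] guarantees the result
    stays in bounds, and Δ → 0 as n → N.  λ is drawn before β.
    """
    if N <= 0:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError("generation index n must lie in [0, N]")
    if lam is None:
        lam = int(rng.integers(2))
    if beta is None:
        beta = float(rng.uniform())
    exponent = (1.0 - n / N) ** q
    dist = (upper - y) if lam == 0 else (y - lower)
    delta = dist * (1.0 - beta ** exponent)
    return y + delta if lam == 0 else y - delta


@dataclass
class EvolveResult:
    best: Chromosome
    trace: list[float] = field(default_factory=list)   # best-ever fitness per generation
    mean_trace: list[float] = field(default_factory=list)


def _evaluate(fitness_fn, genes: np.ndarray, generation: int) -> float:
    f = float(fitness_fn(genes))
    if not np.isfinite(f) or f < 0:
        raise RuntimeError(
            f"fitness function returned {f!r} at generation {generation}; "
            "expected a finite nonnegative value")
    return f


def evolve(initial_population: np.ndarray, fitness_fn,
           config: RCGAConfig, rng: np.random.Generator) -> EvolveResult:
    """Run the generational loop and return the best-ever chromosome.

    ``initial_population`` is a (pop_size, L) array of gene vectors.  The
    loop stops after ``config.generations`` generations or as soon as the
    best-ever fitness reaches ``config.target_fitness``.
    """
    pop_genes = np.array(initial_population, dtype=float)
    if pop_genes.ndim != 2:
        raise ValueError("initial_population must be a 2-D (pop, genes) array")
    lo, hi = config.lower_bound, config.upper_bound
    if pop_genes.min() < lo or pop_genes.max() > hi:
        raise ValueError("initial genes violate the configured bounds")
    population = [Chromosome(g.copy(), _evaluate(fitness_fn, g, 0)) for g in pop_genes]
    best = min(population, key=lambda c: c.fitness).copy()
    trace: list[float] = []
    mean_trace: list[float] = []

    n_genes = pop_genes.shape[1]
    for gen in range(1, config.generations + 1):
        if config.target_fitness is not None and best.fitness <= config.target_fitness:
            break
        fitnesses = np.array([c.fitness for c in population])
        weights = selection_weights(fitnesses)
        new_population = [best.copy()]               # elitism of 1
        while len(new_population) < config.population_size:
            i1 = roulette_spin(weights, rng)
            i2 = roulette_spin(weights, rng)
            parent = population[i1]
            child = parent.genes.copy()
            if rng.uniform() < config.crossover_prob:
                other = population[i2].genes
                for k in range(n_genes):
                    child[k] = blx_crossover(parent.genes[k], other[k],
                                             config.blx_mu, lo, hi, rng)
            for k in range(n_genes):
                if rng.uniform() < config.mutation_prob:
                    child[k] = nonuniform_mutate(child[k], gen, config.generations,
                                                 config.mutation_q, lo, hi, rng)
            if np.array_equal(child, parent.genes):
                new_population.append(parent.copy())
                continue
            f_child = _evaluate(fitness_fn, child, gen)
            # greedy survivor rule: the offspring enters only if not worse
            if f_child <= parent.fitness:
                new_population.append(Chromosome(child, f_child))
            else:
                new_population.append(parent.copy())
        population = new_population
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
        trace.append(best.fitness)
        mean_trace.append(float(np.mean([c.fitness for c in population])))
    return EvolveResult(best, trace, mean_trace)


def random_population(pop_size: int, n_genes: int, lower: float, upper: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform random gene matrix within bounds."""
    return rng.uniform(lower, upper, size=(pop_size, n_genes))


def run_rcga(fitness_fn, n_genes: int, config: RCGAConfig,
             rng: np.random.Generator | None = None) -> EvolveResult:
    """Convenience driver: random initial population, optional restarts.

    With ``config.restarts > 1`` the whole evolution is repeated from fresh
    random populations and the best result across restarts is returned;
    restarts stop early once ``config.target_fitness`` is reached.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    best_result: EvolveResult | None = None
    for _ in range(max(config.restarts, 1)):
        pop = random_population(config.population_size, n_genes,
                                config.lower_bound, config.upper_bound, rng)
        result = evolve(pop, fitness_fn, config, rng)
        if best_result is None or result.best.fitness < best_result.best.fitness:
            best_result = result
        if (config.target_fitness is not None
                and best_result.best.fitness <= config.target_fitness):
            break
    return best_result
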