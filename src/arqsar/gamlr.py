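"""Genetic-algorithm descriptor selection over multiple linear regression.

Each chromosome is a fixed-size set of descriptor column indices. Its model is
an ordinary-least-squares fit (intercept always included) and its fitness is
the Friedman lack-of-fit score

    LOF = SSE / (1 - (c + d*p) / n)**2

where SSE is the training sum of squared errors, p the number of descriptors,
c the number of basis functions (p + 1: descriptors plus intercept), d a
smoothness factor (default 0.5) and n the training-set size. LOF penalises
model size, so the GA trades fit quality against parsimony. Lower is better.

The GA itself is a minimal generational scheme: tournament selection (size 2),
uniform subset crossover with duplicate repair, per-gene index-replacement
mutation, and elitism. All randomness flows from one seeded generator, so a
run is a pure function of (data, config).

For speed the GA evaluates subsets against a precomputed Gram matrix
(X~'X~ and X~'y over all columns with the intercept), solving each subset's
normal equations by Cholesky factorisation; the public :func:`fit_ols` uses a
rank-checked least-squares solve, and the two agree to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .errors import ConfigError, DegeneratePenaltyError, SingularFitError
from .tables import DescriptorTable, ModelSpec

__all__ = ["FitResult", "GAConfig", "Chromosome", "fit_ols", "friedman_lof", "run_ga"]


@dataclass(frozen=True)
class FitResult:
    """An OLS fit of y on a descriptor subset (intercept included)."""

    model: ModelSpec
    sse: float
    residuals: np.ndarray
    n: int
    c: int          # number of basis functions: p_terms + 1
    p_terms: int

    def lof(self, d: float = 0.5) -> float:
        return friedman_lof(self.sse, self.c, d, self.p_terms, self.n)


@dataclass(frozen=True)
class GAConfig:
    """Search parameters. Defaults follow the published modelling protocol
    (population 200, up to 10000 generations, mutation probability 0.05,
    smoothness 0.5) with a stagnation early-stop making full-length runs
    affordable."""

    population_size: int = 200
    max_generations: int = 10000
    mutation_probability: float = 0.05
    model_size: int = 4
    smoothing_d: float = 0.5
    seed: int = 0
    elitism_count: int = 2
    crossover_probability: float = 0.9
    stagnation_patience: int = 500

    def validate(self, n_descriptors: int) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not (1 <= self.model_size <= n_descriptors):
            raise ConfigError(
                f"model_size {self.model_size} outside [1, {n_descriptors}]"
            )
        if not (0.0 <= self.mutation_probability <= 1.0):
            raise ConfigError("mutation_probability must be in [0, 1]")
        if not (0.0 <= self.crossover_probability <= 1.0):
            raise ConfigError("crossover_probability must be in [0, 1]")
        if self.max_generations < 0 or self.stagnation_patience < 0:
            raise ConfigError("generation counts must be >= 0")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ConfigError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class Chromosome:
    """A candidate descriptor subset with its Friedman LOF fitness."""

    descriptor_indices: tuple[int, ...]
    fitness: float

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.descriptor_indices))
        if len(set(idx)) != len(idx):
            raise ConfigError("chromosome has duplicate descriptor indices")
        object.__setattr__(self, "descriptor_indices", idx)


def fit_ols(table: DescriptorTable, y: Sequence[float]) -> FitResult:
    """Ordinary least squares of y on all columns of ``table`` plus intercept.

    Raises :class:`SingularFitError` on a rank-deficient design and
    :class:`ConfigError` when n <= p + 1 (no residual degrees of freedom).
    """
    y = np.asarray(y, dtype=float)
    n, p = table.n_compounds, table.n_descriptors
    if len(y) != n:
        raise ConfigError(f"y has length {len(y)}, table has {n} compounds")
    if n <= p + 1:
        raise ConfigError(f"need n > p + 1 (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), table.values])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        raise SingularFitError(
            f"design matrix rank {rank} < {p + 1}; collinear or duplicated descriptors"
        )
    residuals = y - design @ coef
    sse = float(residuals @ residuals)
    model = ModelSpec(
        descriptor_names=table.descriptor_names,
        coefficients=tuple(coef[1:]),
        intercept=float(coef[0]),
        n_train=n,
    )
    return FitResult(model=model, sse=sse, residuals=residuals, n=n, c=p + 1, p_terms=p)


def friedman_lof(sse: float, c: int, d: float, p: int, n: int) -> float:
    """Friedman lack-of-fit score SSE / (1 - (c + d*p)/n)**2 (lower = fitter)."""
    if n <= 0:
        raise DegeneratePenaltyError("n must be positive")
    if sse < 0:
        raise ValueError("SSE cannot be negative")
    penalty = 1.0 - (c + d * p) / n
    if penalty <= 0:
        raise DegeneratePenaltyError(
            f"(c + d*p) = {c + d * p} >= n = {n}: LOF denominator is not positive"
        )
    return sse / penalty**2


# ---------------------------------------------------------------------------
# GA internals
# ---------------------------------------------------------------------------

class _GramEvaluator:
    """Subset SSE via precomputed Gram matrix + per-subset Cholesky solve."""

    def __init__(self, table: DescriptorTable, y: np.ndarray):
        design = np.column_stack([np.ones(table.n_compounds), table.values])
        self.gram = design.T @ design
        self.xty = design.T @ y
        self.yty = float(y @ y)
        self.n = table.n_compounds

    def sse(self, indices: tuple[int, ...]) -> float:
        """SSE of the OLS fit on the given columns; +inf for singular subsets."""
        cols = np.concatenate(([0], np.asarray(indices, dtype=int) + 1))
        g = self.gram[np.ix_(cols, cols)]
        b = self.xty[cols]
        try:
            cho = scipy.linalg.cho_factor(g, check_finite=False)
        except scipy.linalg.LinAlgError:
            return np.inf
        coef = scipy.linalg.cho_solve(cho, b, check_finite=False)
        return max(self.yty - float(coef @ b), 0.0)


def _random_subset(rng: np.random.Generator, n_cols: int, k: int) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(n_cols, size=k, replace=False).tolist()))


def _mutate(
    rng: np.random.Generator, subset: tuple[int, ...], n_cols: int, prob: float
) -> tuple[int, ...]:
    genes = list(subset)
    for slot in range(len(genes)):
        if rng.random() < prob:
            pool = [i for i in range(n_cols) if i not in genes]
            if pool:
                genes[slot] = pool[rng.integers(len(pool))]
    return tuple(sorted(genes))


def _crossover(
    rng: np.random.Generator, a: tuple[int, ...], b: tuple[int, ...], n_cols: int
) -> tuple[int, ...]:
    """Uniform subset crossover: draw each gene from either parent, repair
    duplicates by sampling unused indices."""
    k = len(a)
    child: list[int] = []
    for ga, gb in zip(a, b):
        pick = ga if rng.random() < 0.5 else gb
        if pick not in child:
            child.append(pick)
    pool = [i for i in set(a) | set(b) if i not in child]
    rng.shuffle(pool)
    while len(child) < k and pool:
        child.append(pool.pop())
    while len(child) < k:  # both parents nearly identical: resample fresh genes
        cand = int(rng.integers(n_cols))
        if cand not in child:
            child.append(cand)
    return tuple(sorted(child))


def run_ga(
    table: DescriptorTable,
    y: Sequence[float],
    config: GAConfig,
    *,
    top_k: int = 10,
) -> list[tuple[Chromosome, FitResult]]:
    """Search descriptor subsets of size ``config.model_size`` minimising LOF.

    Returns the ``top_k`` distinct best chromosomes ever evaluated, each with
    a full :class:`FitResult`, sorted by ascending fitness. Reproducible given
    ``config.seed``; stops at ``max_generations`` or after
    ``stagnation_patience`` generations without improvement of the best LOF.
    """
    y = np.asarray(y, dtype=float)
    config.validate(table.n_descriptors)
    n, k = table.n_compounds, config.model_size
    if n <= k + 1:
        raise ConfigError(f"need n > model_size + 1 (got n={n}, model_size={k})")
    rng = np.random.default_rng(config.seed)
    evaluator = _GramEvaluator(table, y)
    d = config.smoothing_d
    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: tuple[int, ...]) -> float:
        fit = cache.get(subset)
        if fit is None:
            sse = evaluator.sse(subset)
            fit = np.inf if not np.isfinite(sse) else friedman_lof(sse, k + 1, d, k, n)
            cache[subset] = fit
        return fit

    population = [_random_subset(rng, table.n_descriptors, k) for _ in range(config.population_size)]
    for subset in population:
        fitness(subset)
    best = min(population, key=fitness)
    since_improvement = 0

    for _ in range(config.max_generations):
        ranked = sorted(population, key=fitness)
        next_pop = ranked[: config.elitism_count]
        seen = set(next_pop)
        while len(next_pop) < config.population_size:
            # tournament selection, size 2
            parents = []
            for _ in range(2):
                i, j = rng.integers(len(population)), rng.integers(len(population))
                a, b = population[i], population[j]
                parents.append(a if fitness(a) <= fitness(b) else b)
            if rng.random() < config.crossover_probability:
                child = _crossover(rng, parents[0], parents[1], table.n_descriptors)
            else:
                child = parents[0]
            child = _mutate(rng, child, table.n_descriptors, config.mutation_probability)
            # keep the population duplicate-free: a clone of an existing member
            # is forced through extra single-gene mutations until it is novel,
            # which preserves search diversity on wide descriptor tables
            guard = 0
            while child in seen and guard < 50:
                child = _mutate(rng, child, table.n_descriptors, 1.0 / k)
                guard += 1
            fitness(child)
            seen.add(child)
            next_pop.append(child)
        population = next_pop
        gen_best = min(population, key=fitness)
        if fitness(gen_best) < fitness(best):
            best = gen_best
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.stagnation_patience:
                break

    ranked_all = sorted((s for s in cache if np.isfinite(cache[s])), key=lambda s: cache[s])
    results: list[tuple[Chromosome, FitResult]] = []
    for subset in ranked_all[:top_k]:
        names = tuple(table.descriptor_names[i] for i in subset)
        fit = fit_ols(table.select_descriptors(names), y)
        results.append((Chromosome(subset, cache[subset]), fit))
    return results
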