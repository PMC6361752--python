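"""Genetic Function Approximation over linear descriptor-subset models.

A genetic algorithm evolves a population of descriptor subsets; each
subset is scored by fitting an OLS model and computing Friedman's
lack-of-fit (LOF), so the search trades goodness of fit against model
size automatically. Only linear terms are used. Highly correlated
descriptor pairs are removed up front, subsets are kept between a minimum
and maximum term count, the single best model survives each generation
unchanged (elitism), and parents are chosen by rank-based selection with
single-point crossover on the union of their term sets plus a one-term
add/remove/replace mutation.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .descriptors import DescriptorMatrix
from .errors import PoolError, ZfqsarError
from .validation import (
    LinearQSARModel,
    ModelStats,
    fit_mlr,
    friedman_lof,
    model_statistics,
)

Subset = tuple[str, ...]


@dataclass(frozen=True)
class GFAConfig:
    """Search settings. Defaults mirror the study's reported GA settings
    (population 100, up to 5000 generations, 2-6 terms, pairwise
    correlation cap 0.95); the selection/crossover/mutation kernels and
    their rates are this package's own choices, as is the early-stopping
    patience (0 disables it)."""

    population_size: int = 100
    max_generations: int = 5000
    term_count_min: int = 2
    term_count_max: int = 6
    correlation_threshold: float = 0.95
    smoothing_d: float = 0.5
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    elitism_count: int = 1
    patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.term_count_min <= self.term_count_max):
            raise ZfqsarError("need 2 <= term_count_min <= term_count_max")
        if not (0 < self.correlation_threshold <= 1):
            raise ZfqsarError("correlation_threshold must be in (0, 1]")
        for name in ("mutation_rate", "crossover_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ZfqsarError(f"{name} must be in [0, 1]")
        if self.population_size < 2:
            raise ZfqsarError("population_size must be >= 2")


@dataclass
class GFAResult:
    """Ranked final population and the trace of the best LOF per generation."""

    final_population: list[tuple[Subset, LinearQSARModel | None, ModelStats | None]]
    generations_run: int
    fitness_trace: list[float]
    evaluations: dict[Subset, float] = field(repr=False, default_factory=dict)

    @property
    def best(self) -> tuple[Subset, LinearQSARModel | None, ModelStats | None]:
        return self.final_population[0]


def correlation_prefilter(
    X: DescriptorMatrix, threshold: float = 0.95
) -> DescriptorMatrix:
    """Drop one member of each descriptor pair with |Pearson r| >= threshold.

    Columns are visited in a deterministic order (descending variance,
    name as tie-break); a column is kept only if it is below the
    threshold against every column already kept, so the higher-variance
    member of a collinear pair survives.
    """
    n_cols = len(X.descriptor_names)
    variances = np.var(X.values, axis=0)
    order = sorted(range(n_cols), key=lambda j: (-variances[j], X.descriptor_names[j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X.values, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=1.0)  # constant columns: treat as collinear
    kept: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) < threshold for k in kept):
            kept.append(j)
    kept.sort()  # restore original column order
    return DescriptorMatrix(
        compound_ids=list(X.compound_ids),
        descriptor_names=[X.descriptor_names[j] for j in kept],
        values=X.values[:, kept],
    )


def initialize_population(
    pool: Sequence[str], config: GFAConfig, rng: np.random.Generator | None = None
) -> list[Subset]:
    """Random subsets of uniform-random size in [term_count_min, term_count_max]."""
    if len(pool) < config.term_count_max:
        raise PoolError(
            f"descriptor pool of {len(pool)} is smaller than "
            f"term_count_max={config.term_count_max}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = list(pool)
    population = []
    for _ in range(config.population_size):
        size = int(rng.integers(config.term_count_min, config.term_count_max + 1))
        members = rng.choice(len(pool), size=size, replace=False)
        population.append(tuple(sorted(pool[i] for i in members)))
    return population


def _evaluate(
    subset: Subset,
    X: DescriptorMatrix,
    y: np.ndarray,
    config: GFAConfig,
    cache: dict[Subset, float],
) -> float:
    """LOF fitness of a subset; singular/over-parameterized designs score inf."""
    if subset in cache:
        return cache[subset]
    try:
        model = fit_mlr(X, y, subset)
        residuals = y - model.predict(X)
        sse = float(np.sum(residuals**2))
        lof = friedman_lof(sse, y.size, len(subset) + 1, len(subset), config.smoothing_d)
    except ZfqsarError:
        lof = float("inf")
    cache[subset] = lof
    return lof


def _clamp(
    terms: list[str],
    pool: Sequence[str],
    config: GFAConfig,
    rng: np.random.Generator,
) -> Subset:
    terms = list(dict.fromkeys(terms))  # dedupe, order-preserving
    while len(terms) > config.term_count_max:
        terms.pop(int(rng.integers(len(terms))))
    absent = [p for p in pool if p not in terms]
    while len(terms) < config.term_count_min and absent:
        terms.append(absent.pop(int(rng.integers(len(absent)))))
    return tuple(sorted(terms))


def _mutate(
    terms: Subset, pool: Sequence[str], config: GFAConfig, rng: np.random.Generator
) -> Subset:
    terms_list = list(terms)
    absent = [p for p in pool if p not in terms]
    op = rng.integers(3)  # 0: add, 1: remove, 2: replace
    if op == 0 and absent and len(terms_list) < config.term_count_max:
        terms_list.append(absent[int(rng.integers(len(absent)))])
    elif op == 1 and len(terms_list) > config.term_count_min:
        terms_list.pop(int(rng.integers(len(terms_list))))
    elif op == 2 and absent:
        terms_list[int(rng.integers(len(terms_list)))] = absent[
            int(rng.integers(len(absent)))
        ]
    return _clamp(terms_list, pool, config, rng)


def evolve_generation(
    population: list[Subset],
    X: DescriptorMatrix,
    y: Sequence[float],
    config: GFAConfig,
    rng: np.random.Generator | None = None,
    cache: dict[Subset, float] | None = None,
    pool: Sequence[str] | None = None,
) -> list[Subset]:
    """One generation: elitism, rank selection, crossover, mutation.

    ``pool`` is the full descriptor pool mutations may draw from; it
    defaults to X's columns so terms lost from the population can
    re-enter.
    """
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if cache is None:
        cache = {}
    if pool is None:
        pool = list(X.descriptor_names)
    fitness = [_evaluate(s, X, y, config, cache) for s in population]
    ranked = sorted(range(len(population)), key=lambda i: (fitness[i], population[i]))
    # rank-based selection weights for the crossover partner: best gets
    # weight N, worst gets 1
    n = len(population)
    weights = np.empty(n)
    for rank, idx in enumerate(ranked):
        weights[idx] = n - rank
    weights /= weights.sum()
    # elites survive unchanged; every other member (in rank order) breeds
    # with a rank-selected partner, so zero crossover and mutation rates
    # reproduce the population exactly up to ordering
    next_gen: list[Subset] = [population[i] for i in ranked[: config.elitism_count]]
    for slot in ranked[config.elitism_count :]:
        p1 = population[slot]
        if rng.random() < config.crossover_rate:
            p2 = population[int(rng.choice(n, p=weights))]
            cut1 = int(rng.integers(len(p1) + 1))
            cut2 = int(rng.integers(len(p2) + 1))
            child = list(p1[:cut1]) + list(p2[cut2:])
        else:
            child = list(p1)
        child_subset = _clamp(child, pool, config, rng)
        if rng.random() < config.mutation_rate:
            child_subset = _mutate(child_subset, pool, config, rng)
        next_gen.append(child_subset)
    return next_gen


def gfa_search(
    X: DescriptorMatrix, y: Sequence[float], config: GFAConfig | None = None
) -> GFAResult:
    """Full search: prefilter, initialize, evolve, rank the final population.

    Stops early when the best LOF has not improved for ``config.patience``
    consecutive generations (patience 0 runs all max_generations).
    """
    if config is None:
        config = GFAConfig()
    y = np.asarray(y, dtype=float)
    X = correlation_prefilter(X, config.correlation_threshold)
    pool = list(X.descriptor_names)
    rng = np.random.default_rng(config.seed)
    population = initialize_population(pool, config, rng)
    cache: dict[Subset, float] = {}
    trace: list[float] = []
    best = float("inf")
    stale = 0
    generations = 0
    for _ in range(config.max_generations):
        population = evolve_generation(population, X, y, config, rng, cache)
        generations += 1
        gen_best = min(_evaluate(s, X, y, config, cache) for s in population)
        if gen_best < best - 1e-15:
            best = gen_best
            stale = 0
        else:
            stale += 1
        trace.append(best)
        if config.patience > 0 and stale >= config.patience:
            break
    final: list[tuple[Subset, LinearQSARModel | None, ModelStats | None]] = []
    for subset in sorted(set(population), key=lambda s: (cache.get(s, float("inf")), s)):
        try:
            model = fit_mlr(X, y, subset)
            stats = model_statistics(model, X, y, config.smoothing_d)
        except ZfqsarError:
            model, stats = None, None
        final.append((subset, model, stats))
    return GFAResult(
        final_population=final,
        generations_run=generations,
        fitness_trace=trace,
        evaluations=cache,
    )


def exhaustive_best_subset(
    X: DescriptorMatrix, y: Sequence[float], config: GFAConfig | None = None
) -> tuple[Subset, float]:
    """Enumerate every subset of allowed size and return the LOF optimum.

    Practical only for small descriptor pools; used as the ground-truth
    reference for the genetic search.
    """
    from itertools import combinations

    if config is None:
        config = GFAConfig()
    y = np.asarray(y, dtype=float)
    X = correlation_prefilter(X, config.correlation_threshold)
    cache: dict[Subset, float] = {}
    best_subset: Subset = ()
    best_lof = float("inf")
    for size in range(config.term_count_min, config.term_count_max + 1):
        for combo in combinations(sorted(X.descriptor_names), size):
            lof = _evaluate(combo, X, y, config, cache)
            if lof < best_lof:
                best_subset, best_lof = combo, lof
    return best_subset, best_lof


def train_test_split_ids(
    ids: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded split into training/test identifier lists.

    The training count is the fraction rounded to the nearest integer
    (19 compounds at 0.8 give 15), sampled without replacement.
    """
    ids = list(ids)
    if not (0 < fraction < 1):
        raise ZfqsarError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(round(len(ids) * fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test
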