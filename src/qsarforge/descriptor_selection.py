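"""Descriptor-subset selection: all-subsets enumeration and a genetic algorithm.

Variable selection for small-n QSAR follows a two-stage protocol: subsets
of one or two descriptors are enumerated exhaustively, and larger
combinations are searched with a genetic algorithm over binary inclusion
masks (GA-MLR). The selection fitness is the leave-one-out Q² by default —
the cross-validated statistic guards against the overfitting that raw R²
invites when the descriptor pool dwarfs the compound count — with R²
available as an alternative.

GA operators: tournament selection (size 2), uniform crossover, mutation
applied per individual as a single random bit flip, one elite carried over
unchanged, and hard repair of any chromosome exceeding the subset-size cap.
The configured mutation rate is the per-individual probability of
undergoing a flip; at the conventional setting of 0.6 a per-bit reading
would randomise most of the chromosome every generation and the search
would not converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .dataset_io import QsarDataset, DatasetError
from . import mlr_core
from .mlr_core import RankDeficiencyError

#: Fitness assigned to infeasible subsets inside a search (rank deficient or
#: too large for the available degrees of freedom).
INFEASIBLE = float("-inf")

#: Guard on the number of subsets exhaustive_search will enumerate.
MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the descriptor-subset search.

    The GA defaults — population 800, 3000 generations, mutation rate 0.6 —
    follow the convention of GA-MLR QSAR software; ``max_subset_size``
    defaults to 4, the largest model size the package is designed around.
    """

    max_subset_size: int = 4
    fitness_metric: str = "Q2_LOO"   # or "R2"
    ga_population: int = 800
    ga_generations: int = 3000
    ga_mutation_rate: float = 0.6
    ga_crossover_rate: float = 0.9
    ga_elitism: int = 1
    rng_seed: int = 0
    # early stop: end the GA after this many generations without improvement
    # (None disables; the full generation budget is rarely informative on
    # pools small enough to fit in memory)
    ga_patience: int | None = 200

    def __post_init__(self) -> None:
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if self.fitness_metric not in ("Q2_LOO", "R2"):
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")
        for name in ("ga_mutation_rate", "ga_crossover_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class SubsetResult:
    """A candidate subset with its fitted model and all diagnostics."""

    descriptor_names: tuple[str, ...]
    fitness: float
    model: "mlr_core.MLRModel | None"
    stats: "mlr_core.FitStats | None"
    loo: "mlr_core.LOOSummary | None"

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.fitness)


def evaluate_subset(
    dataset: QsarDataset,
    subset: Sequence[str],
    metric: str = "Q2_LOO",
    in_search: bool = False,
) -> SubsetResult:
    """Fit OLS on a descriptor subset and score it by the chosen metric.

    Outside a search, infeasible subsets (rank deficiency, insufficient
    degrees of freedom) raise; inside (``in_search=True``) they yield the
    -inf sentinel so the search can move on. Unknown descriptor names always
    raise.
    """
    if not subset:
        raise DatasetError("empty descriptor subset")
    ds = dataset.subset(subset)  # validates names
    try:
        model = mlr_core.fit_ols(ds)
        stats = mlr_core.goodness_of_fit(model, ds)
        loo = mlr_core.loo_cross_validate(ds) if metric == "Q2_LOO" else None
    except (RankDeficiencyError, DatasetError):
        if in_search:
            return SubsetResult(tuple(subset), INFEASIBLE, None, None, None)
        raise
    fitness = loo.Q2 if metric == "Q2_LOO" else stats.R2
    return SubsetResult(tuple(subset), fitness, model, stats, loo)


def _rank_key(res: SubsetResult):
    # fitness desc, then smaller subset, then lexicographic names
    return (-res.fitness, len(res.descriptor_names), res.descriptor_names)


def exhaustive_search(
    dataset: QsarDataset,
    max_size: int = 2,
    metric: str = "Q2_LOO",
) -> list[SubsetResult]:
    """Evaluate every descriptor subset of size 1..max_size, ranked by fitness.

    Ties break deterministically: higher fitness, then smaller subset, then
    lexicographic descriptor names. Refuses pools whose enumeration would
    exceed a million subsets; use :func:`ga_search` there.
    """
    p = dataset.p
    if max_size > p:
        raise DatasetError(f"max_size {max_size} exceeds pool size {p}")
    total = sum(math.comb(p, k) for k in range(1, max_size + 1))
    if total > MAX_ENUMERATION:
        raise DatasetError(
            f"{total} subsets exceed the enumeration guard ({MAX_ENUMERATION}); use ga_search")
    results = [
        evaluate_subset(dataset, subset, metric, in_search=True)
        for k in range(1, max_size + 1)
        for subset in combinations(dataset.descriptor_names, k)
    ]
    return sorted(results, key=_rank_key)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _mask_to_names(mask: np.ndarray, names: Sequence[str]) -> tuple[str, ...]:
    return tuple(nm for nm, bit in zip(names, mask) if bit)


def _repair(mask: np.ndarray, max_size: int, rng: np.random.Generator) -> np.ndarray:
    """Enforce 1 <= popcount <= max_size by random bit edits."""
    active = np.flatnonzero(mask)
    if len(active) > max_size:
        drop = rng.choice(active, size=len(active) - max_size, replace=False)
        mask = mask.copy()
        mask[drop] = False
    elif len(active) == 0:
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def ga_search(dataset: QsarDataset, config: SelectionConfig | None = None) -> SubsetResult:
    """Genetic-algorithm subset search over binary descriptor masks.

    Chromosomes are length-p inclusion masks capped at
    ``config.max_subset_size`` active bits. Each generation applies
    tournament selection (size 2), uniform crossover, a per-individual
    single-bit-flip mutation, and elitism; the best subset ever evaluated is
    returned. Fully reproducible for a given ``rng_seed``. Fitness values
    are cached per subset, so a converged search costs far fewer model fits
    than population x generations.
    """
    config = config or SelectionConfig()
    p = dataset.p
    names = dataset.descriptor_names
    if p < 2:
        raise DatasetError("GA search needs a pool of at least 2 descriptors")
    if config.max_subset_size > p:
        raise DatasetError(f"max_subset_size {config.max_subset_size} exceeds pool size {p}")

    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple[str, ...], SubsetResult] = {}

    def score(mask: np.ndarray) -> SubsetResult:
        key = _mask_to_names(mask, names)
        if key not in cache:
            cache[key] = evaluate_subset(dataset, key, config.fitness_metric, in_search=True)
        return cache[key]

    # initial population: random masks with 1..max_subset_size active bits
    low = min(2, config.max_subset_size)
    pop = np.zeros((config.ga_population, p), dtype=bool)
    for i in range(config.ga_population):
        k = int(rng.integers(low, config.max_subset_size + 1))
        pop[i, rng.choice(p, size=k, replace=False)] = True

    results = [score(m) for m in pop]
    best = min(results, key=_rank_key)
    stall = 0

    for _ in range(config.ga_generations):
        fitness = np.array([r.fitness for r in results])
        # tournament selection, size 2
        a = rng.integers(config.ga_population, size=config.ga_population)
        b = rng.integers(config.ga_population, size=config.ga_population)
        winners = np.where(fitness[a] >= fitness[b], a, b)
        parents = pop[winners]

        children = parents.copy()
        for i in range(0, config.ga_population - 1, 2):
            if rng.random() < config.ga_crossover_rate:
                swap = rng.random(p) < 0.5
                c1, c2 = children[i].copy(), children[i + 1].copy()
                children[i, swap], children[i + 1, swap] = c2[swap], c1[swap]
        for i in range(config.ga_population):
            if rng.random() < config.ga_mutation_rate:
                j = int(rng.integers(p))
                children[i, j] = ~children[i, j]
            children[i] = _repair(children[i], config.max_subset_size, rng)

        # elitism: overwrite the first slots with the current best masks
        elite_order = sorted(range(len(results)), key=lambda i: _rank_key(results[i]))
        for slot, idx in enumerate(elite_order[: config.ga_elitism]):
            children[slot] = pop[idx]

        pop = children
        results = [score(m) for m in pop]
        gen_best = min(results, key=_rank_key)
        if _rank_key(gen_best) < _rank_key(best):
            best = gen_best
            stall = 0
        else:
            stall += 1
            if config.ga_patience is not None and stall >= config.ga_patience:
                break

    if not best.feasible:
        raise DatasetError("GA found no feasible subset under the configured constraints")
    return best


def rank_table(results: Iterable[SubsetResult]) -> "list[dict]":
    """Flatten ranked subset results for CSV export."""
    rows = []
    for rank, res in enumerate(results, start=1):
        rows.append({
            "rank": rank,
            "subset": "+".join(res.descriptor_names),
            "size": len(res.descriptor_names),
            "fitness": res.fitness,
            "R2": res.stats.R2 if res.stats else float("nan"),
            "Q2": res.loo.Q2 if res.loo else float("nan"),
            "s": res.stats.s if res.stats else float("nan"),
            "F": res.stats.F if res.stats else float("nan"),
        })
    return rows
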