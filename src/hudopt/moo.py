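"""Multi-objective (Pareto) optimization of interface designs.

The two objectives are minimized jointly: predicted cognitive load
(NASA-TLX from the surrogate) and negative AOI attention coverage from
the importance predictor, so a solution is better when it demands less
workload and concentrates predicted attention on the module boxes.

The loop is the standard generational Pareto GA (NSGA-II): parents and
offspring are pooled each generation, ranked by fast non-dominated
sorting, and the next population is filled front by front with
crowding-distance tie-breaking.  Variation reuses the single-objective
operators (roulette-free binary tournament is replaced here by rank
sampling via the pooled selection; crossover, mutation and one-hot
repair are identical).  An optional weighted-sum scalarization turns
the objective pair into a single fitness for the plain GA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import codec
from .errors import ConfigError
from .ga import (
    GAConfig,
    array_to_bits,
    bits_to_array,
    crossover_single_point,
    mutate_bitflip,
    repair_onehot,
)
from .render import attention_objective, default_template

__all__ = [
    "ParetoFront",
    "fast_nondominated_sort",
    "crowding_distance",
    "dominates",
    "make_objectives",
    "scalarize",
    "run_moo_ga",
    "MultiObjectiveOptimizer",
]


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff a is no worse than b in every objective and better in one."""
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(F: np.ndarray) -> list[list[int]]:
    """Partition row indices of objective matrix F into Pareto fronts."""
    n = len(F)
    S: list[list[int]] = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if dominates(F[p], F[q]):
                S[p].append(q)
            elif dominates(F[q], F[p]):
                counts[p] += 1
        if counts[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt: list[int] = []
        for p in fronts[i]:
            for q in S[p]:
                counts[q] -= 1
                if counts[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of each row within one front."""
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], j] - F[order[0], j]
        if span == 0:
            continue
        d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


@dataclass(frozen=True)
class ParetoFront:
    """Mutually non-dominated (chromosome, objective-vector) pairs."""

    codes: tuple[str, ...]
    objectives: np.ndarray  # (n, 2): [predicted load, -coverage]

    def __post_init__(self) -> None:
        F = np.asarray(self.objectives, dtype=float)
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j and dominates(F[i], F[j]):
                    raise ConfigError("front contains a dominated member")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def members(self) -> list[tuple[str, tuple[float, float]]]:
        return [(c, tuple(o)) for c, o in zip(self.codes, self.objectives)]


def make_objectives(surrogate, ivpm_model, template=None) -> Callable[[np.ndarray], np.ndarray]:
    """Objective function pop (n, 26) -> (n, 2) [predicted load, -coverage].

    Rendering plus a forward pass per distinct design dominates the
    cost, so results are memoized by chromosome string (there are only
    8192 valid designs).
    """
    template = template or default_template()
    cache: dict[str, tuple[float, float]] = {}

    def objectives(pop: np.ndarray) -> np.ndarray:
        loads = surrogate.predict(pop.astype(float))
        out = np.empty((len(pop), 2))
        for i, ind in enumerate(pop):
            code = array_to_bits(ind)
            if code not in cache:
                design = codec.decode(code)
                cov = attention_objective(ivpm_model, design, template)
                cache[code] = (float(loads[i]), -cov)
            out[i] = (float(loads[i]), cache[code][1])
        return out

    return objectives


def scalarize(objectives_fn, weights: Sequence[float] = (0.5, 0.5), upper_bound: float = 21.0):
    """Weighted-sum fallback: a single non-negative fitness for the plain GA."""
    w = np.asarray(weights, dtype=float)

    def fitness(pop: np.ndarray) -> np.ndarray:
        F = objectives_fn(pop)
        # both objectives are minimized; shift into a maximized bound
        return np.maximum(upper_bound - (F @ w), 0.0)

    return fitness


class MultiObjectiveOptimizer:
    """NSGA-II loop over one-hot chromosomes; reuses the GA variation operators."""

    def __init__(self, objectives: Callable[[np.ndarray], np.ndarray], config: GAConfig | None = None):
        self.config = config or GAConfig(max_generations=40)
        self.config.validate()
        self.objectives = objectives

    def _select(self, pop: np.ndarray, F: np.ndarray, rng) -> np.ndarray:
        """Binary tournament on (rank, -crowding)."""
        fronts = fast_nondominated_sort(F)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = crowding_distance(F[front])
        i, j = rng.integers(len(pop)), rng.integers(len(pop))
        if (rank[i], -crowd[i]) <= (rank[j], -crowd[j]):
            return pop[i]
        return pop[j]

    def run(self, dataset=None) -> list[ParetoFront]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if cfg.init == "from_dataset":
            if dataset is None:
                raise ConfigError("init='from_dataset' requires a dataset")
            pool = [bits_to_array(c) for c in dataset.codes]
            pop = np.stack([pool[i] for i in rng.integers(len(pool), size=cfg.population_size)])
        else:
            pop = rng.integers(0, 2, size=(cfg.population_size, 26)).astype(np.uint8)
        pop = np.stack([repair_onehot(ind, rng) for ind in pop])
        F = self.objectives(pop)
        snapshots: list[ParetoFront] = []
        for gen in range(cfg.max_generations):
            rate = cfg.mutation_rate_at(gen)
            children = []
            while len(children) < cfg.population_size:
                p1 = self._select(pop, F, rng)
                p2 = self._select(pop, F, rng)
                c1, c2 = crossover_single_point(
                    p1, p2, rng, cfg.crossover_rate, cfg.group_aligned_crossover
                )
                for child in (c1, c2):
                    child = mutate_bitflip(child, rate, rng)
                    children.append(repair_onehot(child, rng))
            child_pop = np.stack(children[: cfg.population_size])
            child_F = self.objectives(child_pop)
            pool_pop = np.concatenate([pop, child_pop])
            pool_F = np.concatenate([F, child_F])
            fronts = fast_nondominated_sort(pool_F)
            next_idx: list[int] = []
            for front in fronts:
                if len(next_idx) + len(front) <= cfg.population_size:
                    next_idx.extend(front)
                else:
                    cd = crowding_distance(pool_F[front])
                    order = np.argsort(-cd, kind="stable")
                    need = cfg.population_size - len(next_idx)
                    next_idx.extend(np.asarray(front)[order[:need]])
                    break
            pop = pool_pop[next_idx]
            F = pool_F[next_idx]
            first = fast_nondominated_sort(F)[0]
            # deduplicate codes so the front is a set
            seen: dict[str, int] = {}
            for i in first:
                seen.setdefault(array_to_bits(pop[i]), i)
            idx = list(seen.values())
            snapshots.append(ParetoFront(tuple(seen.keys()), F[idx].copy()))
        return snapshots


def run_moo_ga(
    surrogate,
    ivpm_model,
    template=None,
    config: GAConfig | None = None,
    dataset=None,
) -> list[ParetoFront]:
    """End-to-end multi-objective run; returns per-generation fronts."""
    objectives = make_objectives(surrogate, ivpm_model, template)
    return MultiObjectiveOptimizer(objectives, config).run(dataset)
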