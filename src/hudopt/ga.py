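"""Single-objective genetic algorithm over 26-bit one-hot chromosomes.

The optimizer evolves a population of interface designs under roulette
(fitness-proportional) selection, single-point crossover, independent
bit-flip mutation and elitism.  Because crossover and mutation can
break the one-hot structure of the encoding, every offspring passes
through a uniform repair step, so each generation consists solely of
strictly decodable designs.

Fitness is any non-negative function of a chromosome.  For cognitive
load the canonical choice is :func:`fitness_from_surrogate`, which maps
a predicted NASA-TLX score ``y`` to ``upper_bound - y`` (default bound
21, the conventional top of the NASA-TLX scale), so minimizing the
predicted load maximizes fitness.

Populations are held as (n, 26) uint8 arrays internally; the public
surface speaks 26-character bit-strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import codec
from .errors import ConfigError

__all__ = [
    "GAConfig",
    "GAHistory",
    "GeneticOptimizer",
    "fitness_from_surrogate",
    "select_roulette",
    "crossover_single_point",
    "mutate_bitflip",
    "repair_onehot",
    "run_ga",
    "bits_to_array",
    "array_to_bits",
]

# (start, width) of each one-hot group in the 26-bit string
_GROUP_BOUNDS = [(s.start, s.stop - s.start) for s in codec.GROUP_SLICES.values()]


def bits_to_array(bits: str) -> np.ndarray:
    return np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")


def array_to_bits(arr: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in arr)


@dataclass(frozen=True)
class GAConfig:
    """Run parameters for the genetic optimizer.

    Defaults follow the study conditions: population 240 (the training
    sample count), crossover rate 0.8, mutation within [0.01, 0.1] --
    annealed linearly from the top to the bottom of that range by
    default -- and roulette selection.  ``max_generations`` and
    ``stall_generations`` are the artifact's own termination rule.
    """

    population_size: int = 240
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_rate_final: float = 0.01
    mutation_schedule: str = "linear_anneal"  # or "fixed"
    selection: str = "roulette"
    max_generations: int = 300
    stall_generations: int = 50
    elitism: int = 1
    init: str = "random_valid"  # or "from_dataset"
    group_aligned_crossover: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate", "mutation_rate_final"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.mutation_schedule not in ("fixed", "linear_anneal"):
            raise ConfigError(f"unknown mutation_schedule {self.mutation_schedule!r}")
        if self.selection != "roulette":
            raise ConfigError(f"unknown selection {self.selection!r}")
        if self.init not in ("random_valid", "from_dataset"):
            raise ConfigError(f"unknown init {self.init!r}")
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if not (0 <= self.elitism < self.population_size):
            raise ConfigError("elitism must be in [0, population_size)")

    def mutation_rate_at(self, generation: int) -> float:
        """Mutation rate for a 0-based generation index."""
        if self.mutation_schedule == "fixed" or self.max_generations <= 1:
            return self.mutation_rate
        frac = generation / (self.max_generations - 1)
        return self.mutation_rate + frac * (self.mutation_rate_final - self.mutation_rate)


@dataclass
class GAHistory:
    """Per-generation trace and final result of one GA run."""

    max_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_codes: list[str] = field(default_factory=list)
    best_code: str = ""
    best_fitness: float = -np.inf
    generation_found: int = -1

    @property
    def n_generations(self) -> int:
        return len(self.max_fitness)


def fitness_from_surrogate(model, upper_bound: float = 21.0) -> Callable[[np.ndarray], np.ndarray]:
    """Fitness = upper_bound - predicted NASA-TLX, vectorized over a population.

    Strictly decreasing in predicted load; non-negative as long as the
    prediction stays below the bound (guaranteed when the bound exceeds
    the maximum training target, since the output unit saturates).
    """
    def fitness(pop: np.ndarray) -> np.ndarray:
        return upper_bound - model.predict(pop.astype(float))

    return fitness


def select_roulette(fitnesses: np.ndarray, rng: np.random.Generator, n_draws: int | None = None) -> np.ndarray:
    """Fitness-proportional sampling of parent indices (with replacement).

    All fitnesses must be non-negative.  An all-zero vector degrades to
    uniform sampling (flagged via a ``RuntimeWarning``).
    """
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ConfigError("roulette selection requires non-negative fitnesses")
    n_draws = len(f) if n_draws is None else n_draws
    total = f.sum()
    if total <= 0:
        import warnings

        warnings.warn("all-zero fitness vector; falling back to uniform selection", RuntimeWarning)
        p = np.full(len(f), 1.0 / len(f))
    else:
        p = f / total
    return rng.choice(len(f), size=n_draws, p=p)


def crossover_single_point(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    rate: float = 0.8,
    group_aligned: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``rate``, swap suffixes at a uniform cut point.

    The cut is drawn from 1..25 on the flat bit-string (or from group
    boundaries when ``group_aligned``).  Offspring are raw; callers
    repair them before decoding.
    """
    a, b = a.copy(), b.copy()
    if rng.random() < rate:
        if group_aligned:
            cuts = [s for s, _ in _GROUP_BOUNDS[1:]]
            cut = int(rng.choice(cuts))
        else:
            cut = int(rng.integers(1, codec.CHROMOSOME_LENGTH))
        a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
    return a, b


def mutate_bitflip(c: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ConfigError(f"mutation rate must lie in [0, 1], got {rate}")
    flips = rng.random(c.shape) < rate
    return np.where(flips, 1 - c, c).astype(np.uint8)


def repair_onehot(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Restore exactly one set bit per group.

    A group with several set bits keeps one of them, chosen uniformly;
    an empty group gets a uniformly chosen bit.  Valid groups pass
    through untouched, so the repair is the identity on valid
    chromosomes.
    """
    out = c.copy()
    for start, width in _GROUP_BOUNDS:
        grp = out[start : start + width]
        ones = np.flatnonzero(grp)
        if len(ones) == 1:
            continue
        keep = int(rng.choice(ones)) if len(ones) else int(rng.integers(width))
        grp[:] = 0
        grp[keep] = 1
    return out


class GeneticOptimizer:
    """Elitist generational GA; see module docstring for the operators.

    ``fitness`` maps an (n, 26) uint8 population to n non-negative
    values.  The per-generation best fitness is monotone non-decreasing
    whenever ``elitism >= 1``.
    """

    def __init__(self, fitness: Callable[[np.ndarray], np.ndarray], config: GAConfig | None = None):
        self.config = config or GAConfig()
        self.config.validate()
        self.fitness = fitness

    def _init_population(self, rng: np.random.Generator, dataset) -> np.ndarray:
        cfg = self.config
        if cfg.init == "from_dataset":
            if dataset is None:
                raise ConfigError("init='from_dataset' requires a dataset")
            pool = [bits_to_array(code) for code in dataset.codes]
            pick = rng.integers(len(pool), size=cfg.population_size)
            pop = np.stack([pool[i] for i in pick])
        else:
            pop = rng.integers(0, 2, size=(cfg.population_size, codec.CHROMOSOME_LENGTH)).astype(np.uint8)
        return np.stack([repair_onehot(ind, rng) for ind in pop])

    def run(self, dataset=None) -> GAHistory:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pop = self._init_population(rng, dataset)
        hist = GAHistory()
        stall = 0
        for gen in range(cfg.max_generations):
            fit = np.asarray(self.fitness(pop), dtype=float)
            order = np.argsort(fit)[::-1]
            best_i = order[0]
            hist.max_fitness.append(float(fit[best_i]))
            hist.mean_fitness.append(float(fit.mean()))
            hist.best_codes.append(array_to_bits(pop[best_i]))
            if fit[best_i] > hist.best_fitness:
                hist.best_fitness = float(fit[best_i])
                hist.best_code = array_to_bits(pop[best_i])
                hist.generation_found = gen
                stall = 0
            else:
                stall += 1
                if stall >= cfg.stall_generations:
                    break
            if gen == cfg.max_generations - 1:
                break
            rate = cfg.mutation_rate_at(gen)
            elite = pop[order[: cfg.elitism]].copy()
            parents = select_roulette(fit, rng, n_draws=cfg.population_size)
            children: list[np.ndarray] = []
            for j in range(0, cfg.population_size, 2):
                p1 = pop[parents[j]]
                p2 = pop[parents[(j + 1) % cfg.population_size]]
                c1, c2 = crossover_single_point(
                    p1, p2, rng, cfg.crossover_rate, cfg.group_aligned_crossover
                )
                for child in (c1, c2):
                    child = mutate_bitflip(child, rate, rng)
                    children.append(repair_onehot(child, rng))
            pop = np.stack(children[: cfg.population_size])
            if cfg.elitism:
                pop[-cfg.elitism :] = elite
        return hist


def run_ga(
    fitness: Callable[[np.ndarray], np.ndarray],
    config: GAConfig | None = None,
    dataset=None,
) -> GAHistory:
    """Run the elitist GA; thin wrapper over :class:`GeneticOptimizer`."""
    return GeneticOptimizer(fitness, config).run(dataset)
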