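"""Population-based parameter search over repeated simulation runs.

A simulation script (or callable) declares its tunable parameters inline via
``get_gene(key, default)`` and reports fitness via ``set_score(score)``; the
identical code runs standalone (defaults apply) or under the evolution
runner, which injects genome values and collects scores.  Each generation the
top ``survivor_fraction`` of the population by score survives unchanged
(elitism, cached scores), and the pool is refilled with clones of uniformly
chosen survivors whose genes are perturbed — by default multiplicatively with
a log-normal factor ``exp(N(0, mutation_sigma))``, a scale-free choice suited
to rate- and size-like parameters (per-gene additive mode available).
Selection is rank-based with a deterministic lineage tie-break, so results do
not depend on evaluation order.  Higher scores are better; minimizers negate.
"""
from __future__ import annotations

import math
import runpy
from dataclasses import dataclass, field

import numpy as np


class EvolutionError(Exception):
    pass


@dataclass
class Genome:
    genes: dict[str, float] = field(default_factory=dict)


@dataclass
class Individual:
    genome: Genome
    generation: int
    lineage: int
    score: float | None = None
    failed: bool = False
    diagnostic: str | None = None

    @property
    def rank_score(self) -> float:
        if self.failed or self.score is None or math.isnan(self.score):
            return -math.inf
        return self.score


@dataclass
class EvoConfig:
    population_size: int = 20
    survivor_fraction: float = 0.3
    generations: int = 10
    mutation_sigma: float = 0.2
    seed: int = 0
    workers: int = 1
    genes: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    mutation_mode: dict[str, str] = field(default_factory=dict)  # name -> "multiplicative"|"additive"

    def __post_init__(self):
        if self.population_size < 2:
            raise EvolutionError("population_size must be >= 2")
        if not 0.0 < self.survivor_fraction <= 1.0:
            raise EvolutionError("survivor_fraction must lie in (0, 1]")
        if self.generations < 1:
            raise EvolutionError("generations must be >= 1")
        if self.mutation_sigma < 0:
            raise EvolutionError("mutation_sigma must be >= 0")
        if math.ceil(self.survivor_fraction * self.population_size) < 1:
            raise EvolutionError("at least one survivor per generation required")


class _EvalContext:
    def __init__(self, genome: dict[str, float]):
        self.genome = genome
        self.requested: dict[str, float] = {}
        self.score: float | None = None
        self.failed = False


_context: _EvalContext | None = None


def get_gene(key: str, default: float) -> float:
    """Evolution-assigned value when the run is managed, else ``default``.

    Under a managed run a key absent from the genome also returns the default
    and registers the gene for the next generation.
    """
    if _context is None:
        return default
    _context.requested[key] = float(default)
    return _context.genome.get(key, float(default))


def set_score(score: float) -> None:
    """Record the fitness of the active individual (higher is better)."""
    if _context is None:
        return
    if _context.score is not None:
        raise EvolutionError("set_score called twice in one evaluation")
    score = float(score)
    if math.isnan(score):
        _context.failed = True
    _context.score = score


def _evaluate(target, genome: dict[str, float]):
    """Run one evaluation under a managed context; returns the context."""
    global _context
    ctx = _EvalContext(genome)
    _context = ctx
    try:
        if callable(target):
            target()
        else:
            runpy.run_path(str(target), run_name="__evolution__")
    finally:
        _context = None
    return ctx


def _mutate(genes: dict[str, float], config: EvoConfig,
            rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name in sorted(genes):
        value = genes[name]
        mode = config.mutation_mode.get(name, "multiplicative")
        if config.mutation_sigma > 0:
            if mode == "additive":
                value = value + rng.normal(0.0, config.mutation_sigma)
            else:
                value = value * math.exp(rng.normal(0.0, config.mutation_sigma))
        if name in config.bounds:
            lo, hi = config.bounds[name]
            value = min(max(value, lo), hi)
        out[name] = value
    return out


def evolve(target, config: EvoConfig, storage=None):
    """Optimize genes of ``target`` (callable or script path).

    Returns ``(best_individual, history)`` where ``history`` is a list of
    per-individual records (generation, lineage, genes, score).  If a
    ``storage`` run folder is given, the history is appended to
    ``evolution.csv`` inside it.  Aborts — with history intact on the raised
    error — if every individual of a generation fails.
    """
    rng = np.random.default_rng(int(config.seed) & 0x7FFFFFFF)
    registry: dict[str, float] = dict(config.genes)
    history: list[dict] = []
    lineage_counter = 0

    def spawn(genes: dict[str, float], generation: int, mutate: bool) -> Individual:
        nonlocal lineage_counter
        lineage_counter += 1
        g = _mutate(genes, config, rng) if mutate else dict(genes)
        return Individual(Genome(g), generation, lineage_counter)

    population = [spawn(registry, 0, mutate=i > 0)
                  for i in range(config.population_size)]

    best: Individual | None = None
    n_survive = math.ceil(config.survivor_fraction * config.population_size)

    for generation in range(config.generations):
        for ind in population:
            if ind.score is not None or ind.failed:
                continue                      # elitism: survivors keep cached scores
            ctx = _evaluate(target, ind.genome.genes)
            for key, default in ctx.requested.items():
                registry.setdefault(key, default)
                ind.genome.genes.setdefault(key, ctx.genome.get(key, default))
            if ctx.score is None:
                ind.failed = True
                ind.diagnostic = "evaluation ended without calling set_score"
            elif ctx.failed:
                ind.failed = True
                ind.score = ctx.score
                ind.diagnostic = "score was NaN"
            else:
                ind.score = ctx.score
        for ind in population:
            history.append({
                "generation": generation, "lineage": ind.lineage,
                **{f"gene_{k}": v for k, v in sorted(ind.genome.genes.items())},
                "score": ind.rank_score,
            })
        ranked = sorted(population, key=lambda i: (-i.rank_score, i.lineage))
        if ranked[0].rank_score == -math.inf:
            _persist(history, storage)
            raise EvolutionError(
                f"all individuals failed in generation {generation} "
                "(history preserved)")
        if best is None or ranked[0].rank_score > best.rank_score:
            best = ranked[0]
        survivors = ranked[:n_survive]
        if generation == config.generations - 1:
            break
        children = []
        # newly discovered genes enter every survivor at their default value
        for ind in survivors:
            for key, default in registry.items():
                ind.genome.genes.setdefault(key, default)
        for _ in range(config.population_size - n_survive):
            parent = survivors[int(rng.integers(len(survivors)))]
            children.append(spawn(parent.genome.genes, generation + 1, mutate=True))
        population = survivors + children

    _persist(history, storage)
    return best, history


def _persist(history, storage):
    if storage is None or not history:
        return
    import pandas as pd
    df = pd.DataFrame(history)
    path = storage.path / "evolution.csv"
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def parse_config_file(path) -> EvoConfig:
    """Plain-text ``key=value`` evolution config.

    Recognized keys: population_size, survivor_fraction, generations,
    mutation_sigma, seed, workers; gene initial values as ``gene:NAME=value``;
    bounds as ``bound:NAME=lo,hi``; per-gene mutation mode as
    ``mutation:NAME=additive``.
    """
    kwargs: dict = {}
    genes: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    modes: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise EvolutionError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("gene:"):
                genes[key[5:]] = float(value)
            elif key.startswith("bound:"):
                lo, hi = (float(v) for v in value.split(","))
                bounds[key[6:]] = (lo, hi)
            elif key.startswith("mutation:"):
                modes[key[9:]] = value
            elif key in ("population_size", "generations", "seed", "workers"):
                kwargs[key] = int(value)
            elif key in ("survivor_fraction", "mutation_sigma"):
                kwargs[key] = float(value)
            else:
                raise EvolutionError(f"unknown config key {key!r}")
    return EvoConfig(genes=genes, bounds=bounds, mutation_mode=modes, **kwargs)
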