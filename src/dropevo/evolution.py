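"""Generational genetic algorithm over droplet formulations.

One GA run is 10 generations of 20 individuals; each individual's recipe is
tested five times and its fitness is the mean of the five counts. A new
generation keeps the 10 roulette-selected parents unchanged and adds 10
offspring built by one-point crossover of randomly paired parents (each
parent used exactly twice) followed by Gaussian mutation. The driver also
supports the environment-swap design: an arena schedule that changes the
obstacle layout at fixed generations, used to study adaptation after abrupt
environmental change.

Seeding is splittable and fully logged: the run seed spawns per-generation
streams, which spawn per-individual and per-repeat seeds, so any single
experiment can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .arena import Arena
from .genome import (
    Genome,
    Individual,
    gaussian_mutation,
    one_point_crossover,
    random_genome,
    roulette_select,
)

__all__ = [
    "GAConfig",
    "GenerationRecord",
    "GARunResult",
    "evaluate_individual",
    "next_generation",
    "generation_stats",
    "run_ga",
]

Evaluator = Callable[[Genome, Arena, int], float]


@dataclass(frozen=True)
class GAConfig:
    """GA run parameters; defaults mirror the platform's standard protocol."""

    generations: int = 10
    pop_size: int = 20
    repeats: int = 5
    n_parents: int = 10
    mutation_variance: float = 0.1
    seed: int = 0
    #: list of ((first_gen, last_gen), arena_id) with inclusive 1-based ranges
    arena_schedule: tuple = (((1, 10), "empty"),)

    def __post_init__(self) -> None:
        if self.n_parents * 2 != self.pop_size:
            raise ValueError("n_parents must be half the population size")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        covered = []
        for (g0, g1), _ in self.arena_schedule:
            covered.extend(range(g0, g1 + 1))
        if sorted(covered) != list(range(1, self.generations + 1)):
            raise ValueError("arena_schedule must cover every generation exactly once")

    def arena_id_for(self, generation: int) -> str:
        for (g0, g1), aid in self.arena_schedule:
            if g0 <= generation <= g1:
                return aid
        raise KeyError(generation)


@dataclass
class GenerationStats:
    mean_fitness: float
    top_quartile: float
    bottom_quartile: float
    genome_sd: tuple[float, float, float, float]


@dataclass
class GenerationRecord:
    index: int                     # 1-based generation number
    individuals: list[Individual]
    arena_id: str
    stats: GenerationStats


@dataclass
class GARunResult:
    config: GAConfig
    generations: list[GenerationRecord]
    #: one row per simulated experiment: (generation, individual, repeat,
    #: genome..., arena_id, seed, fitness)
    evaluation_log: list[dict]

    def evaluations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.evaluation_log)

    def generations_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.generations:
            for i, ind in enumerate(rec.individuals):
                row = {"generation": rec.index, "individual": i, "arena": rec.arena_id}
                row.update(ind.genome.to_dict())
                for r, f in enumerate(ind.repeat_fitnesses):
                    row[f"fitness_{r}"] = f
                row["mean_fitness"] = ind.mean_fitness
                rows.append(row)
        return pd.DataFrame(rows)


def evaluate_individual(
    g: Genome,
    arena: Arena,
    repeats: int,
    evaluator: Evaluator,
    seeds: Sequence[int],
) -> Individual:
    """Run ``repeats`` experiments on one recipe; fitness is their mean."""
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")
    fitnesses = []
    for s in seeds:
        f = float(evaluator(g, arena, int(s)))
        if f < 0 or not np.isfinite(f):
            raise RuntimeError(f"evaluator returned invalid fitness {f} (seed {s})")
        fitnesses.append(f)
    return Individual(genome=g, repeat_fitnesses=fitnesses)


def generation_stats(individuals: list[Individual]) -> GenerationStats:
    """Per-generation summary: mean, top/bottom-quartile individuals, genome SD.

    With the standard 20-individual population the top quartile is the
    fitness of the 5th-ranked individual and the bottom quartile that of the
    15th (descending sort, ties broken by insertion order).
    """
    n = len(individuals)
    fits = np.array([ind.mean_fitness for ind in individuals])
    order = np.argsort(-fits, kind="stable")
    top_idx = int(np.ceil(0.25 * n)) - 1
    bot_idx = int(np.ceil(0.75 * n)) - 1
    genomes = np.array([ind.genome.as_array() for ind in individuals])
    return GenerationStats(
        mean_fitness=float(fits.mean()),
        top_quartile=float(fits[order[top_idx]]),
        bottom_quartile=float(fits[order[bot_idx]]),
        genome_sd=tuple(genomes.std(axis=0)),
    )


def _pair_parents(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random perfect matching on a list holding each parent twice.

    Self-pairs are avoided when a valid shuffle exists (retry, then local
    swap); each parent index appears in exactly two pairs.
    """
    for _ in range(50):
        slots = np.repeat(np.arange(n), 2)
        rng.shuffle(slots)
        pairs = [(int(slots[2 * i]), int(slots[2 * i + 1])) for i in range(n)]
        if all(a != b for a, b in pairs):
            return pairs
    # fall back: fix remaining self-pairs by swapping with another pair
    for i, (a, b) in enumerate(pairs):
        if a == b:
            for j, (c, d) in enumerate(pairs):
                if j != i and c != a and d != a:
                    pairs[i], pairs[j] = (a, d), (c, b)
                    break
    return pairs


def next_generation(
    current: GenerationRecord, cfg: GAConfig, rng: np.random.Generator
) -> list[Genome]:
    """Build the next population: 10 selected parents + 10 crossover offspring."""
    parents = roulette_select(current.individuals, cfg.n_parents, rng)
    genomes = [p.genome for p in parents]
    pairs = _pair_parents(cfg.n_parents, rng)
    for a, b in pairs:
        child = one_point_crossover(parents[a].genome, parents[b].genome, rng)
        child = gaussian_mutation(child, rng, cfg.mutation_variance)
        genomes.append(child)
    return genomes


def run_ga(
    cfg: GAConfig,
    evaluator: Evaluator,
    arenas: dict[str, Arena],
    progress: Callable[[GenerationRecord], None] | None = None,
) -> GARunResult:
    """Execute a full GA run under the configured arena schedule.

    ``arenas`` maps schedule ids to Arena objects. The evaluation log holds
    one entry per simulated experiment (generations x pop_size x repeats).
    """
    for (_, aid) in cfg.arena_schedule:
        if aid not in arenas:
            raise KeyError(f"arena {aid!r} in schedule but not provided")

    ss = np.random.SeedSequence(cfg.seed)
    gen_seeds = ss.spawn(cfg.generations)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    population = [random_genome(init_rng) for _ in range(cfg.pop_size)]

    records: list[GenerationRecord] = []
    log: list[dict] = []
    for gen in range(1, cfg.generations + 1):
        arena_id = cfg.arena_id_for(gen)
        arena = arenas[arena_id]
        gen_ss = gen_seeds[gen - 1]
        ind_seeds = gen_ss.spawn(cfg.pop_size + 1)
        individuals = []
        for i, g in enumerate(population):
            repeat_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in ind_seeds[i].spawn(cfg.repeats)
            ]
            ind = evaluate_individual(g, arena, cfg.repeats, evaluator, repeat_seeds)
            individuals.append(ind)
            for r, (s, f) in enumerate(zip(repeat_seeds, ind.repeat_fitnesses)):
                entry = {"generation": gen, "individual": i, "repeat": r,
                         "arena": arena_id, "seed": s, "fitness": f}
                entry.update(g.to_dict())
                log.append(entry)
        record = GenerationRecord(
            index=gen,
            individuals=individuals,
            arena_id=arena_id,
            stats=generation_stats(individuals),
        )
        records.append(record)
        if progress is not None:
            progress(record)
        if gen < cfg.generations:
            breed_rng = np.random.default_rng(ind_seeds[cfg.pop_size])
            population = next_generation(record, cfg, breed_rng)
    return GARunResult(config=cfg, generations=records, evaluation_log=log)
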