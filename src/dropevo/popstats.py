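"""Population analytics for finished evolutionary runs.

Covers the fitness-weighted average genome (WG) used to characterise what
each environment selects for, one-way ANOVA comparisons of genome components
across environments, the letter-code discretisation of average genomes used
for generation-by-generation heat maps, and the cross-environment test
matrix (how a population evolved in one arena fares in the others).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arena import Arena
from .genome import OILS, Genome, Individual

__all__ = [
    "WeightedGenome",
    "weighted_genome",
    "anova_one_way",
    "heatmap_encode",
    "cross_environment_matrix",
]

#: Row order of the heat-map encoding (as displayed, pentanol first).
HEATMAP_ORDER = ("pentanol", "octanoic", "dep", "octanol")


@dataclass(frozen=True)
class WeightedGenome:
    """Fitness-weighted mean ± sd of each genome component."""

    mean: tuple[float, float, float, float]  # canonical oil order
    sd: tuple[float, float, float, float]

    def as_percent(self) -> str:
        pairs = [f"{100*m:.0f} ± {100*s:.0f}" for m, s in zip(self.mean, self.sd)]
        return "(" + ", ".join(pairs) + ")"


def weighted_genome(individuals: list[Individual]) -> WeightedGenome:
    """Fitness-weighted average genome of a population.

    Weights are the individuals' mean fitnesses; the sd is the weighted
    standard deviation of each component about the weighted mean. All-zero
    fitness leaves the weights undefined and raises.
    """
    if not individuals:
        raise ValueError("empty population")
    w = np.array([ind.mean_fitness for ind in individuals], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all fitnesses are zero: weighted genome undefined")
    w = w / w.sum()
    G = np.array([ind.genome.as_array() for ind in individuals])
    mean = w @ G
    var = w @ (G - mean) ** 2
    return WeightedGenome(mean=tuple(mean), sd=tuple(np.sqrt(var)))


def anova_one_way(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups of observations.

    Returns (F, p). The degenerate all-identical case (zero within- and
    between-group variance) is reported as F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


def heatmap_encode(avg: Genome) -> str:
    """Discretise an average genome into a 4-letter code.

    Each component is rounded (half-up) to one decimal, giving slot
    0..10 capped at 9, mapped to letters A..J. Rows follow the display
    order pentanol, octanoic, DEP, octanol. The letter convention is this
    package's own documented mapping.
    """
    letters = []
    for comp in HEATMAP_ORDER:
        v = getattr(avg, comp)
        slot = min(floor(10 * v + 0.5), 9)
        letters.append(chr(ord("A") + slot))
    return "".join(letters)


def cross_environment_matrix(
    final_gens: dict[str, list[Individual]],
    arenas: dict[str, Arena],
    evaluator,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Test each evolved population in every arena.

    Entry (i, j) is the mean fitness (over individuals and repeats) of the
    final generation evolved in arena i when its recipes are re-run in arena
    j. Rows index the environment of origin, columns the test environment.
    """
    rows = {}
    for o_i, (origin, individuals) in enumerate(final_gens.items()):
        row = {}
        for t_i, (target, arena) in enumerate(arenas.items()):
            fits = []
            for k, ind in enumerate(individuals):
                cell = np.random.SeedSequence([seed, o_i, t_i, k])
                for s in cell.spawn(repeats):
                    fits.append(
                        float(evaluator(ind.genome, arena, int(s.generate_state(1)[0] % (2**31))))
                    )
            row[target] = float(np.mean(fits))
        rows[origin] = row
    return pd.DataFrame.from_dict(rows, orient="index")
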