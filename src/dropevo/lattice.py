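"""Evenly spaced "lattice search" over the formulation simplex.

The combinatorial sweep tests the four oils singly, in pairs, in triples and
all together, at 10% granularity, every member of the chosen subset strictly
positive. At 10% steps this yields 9 compositions per pair (0.1/0.9 ...
0.9/0.1), 36 per triple and 84 for the quadruple: 54 + 144 + 84 = 282
multi-oil formulations, plus the 4 pure oils counted separately. Five
repeats per formulation in one arena give the canonical 1410 experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .arena import Arena
from .genome import OILS, Genome

__all__ = ["LatticeEntry", "LatticePlan", "enumerate_lattice", "run_lattice"]

_CLASS_NAMES = {1: "single", 2: "pair", 3: "triple", 4: "quad"}


@dataclass(frozen=True)
class LatticeEntry:
    genome: Genome
    label: str             # single | pair | triple | quad
    subset: tuple[str, ...]


@dataclass
class LatticePlan:
    formulations: list[LatticeEntry]

    def multi_oil(self) -> list[LatticeEntry]:
        return [e for e in self.formulations if e.label != "single"]

    def singles(self) -> list[LatticeEntry]:
        return [e for e in self.formulations if e.label == "single"]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.formulations:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts


def _compositions(total: int, k: int):
    """All ways to write ``total`` as an ordered sum of k positive integers."""
    if k == 1:
        yield (total,)
        return
    for first in range(1, total - k + 2):
        for rest in _compositions(total - first, k - 1):
            yield (first, *rest)


def enumerate_lattice(granularity: float = 0.1) -> LatticePlan:
    """Enumerate the full lattice plan at the given step size.

    Genomes are built from integer step counts divided once, so each sums to
    1 without accumulation error. Order is lexicographic over the canonical
    oil order (octanol, dep, octanoic, pentanol), singles first.
    """
    steps = 1.0 / granularity
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"1/granularity must be an integer, got {granularity}")
    steps = int(round(steps))
    entries: list[LatticeEntry] = []
    for k in (1, 2, 3, 4):
        for subset_idx in combinations(range(4), k):
            subset = tuple(OILS[i] for i in subset_idx)
            if k == 1:
                vec = np.zeros(4)
                vec[subset_idx[0]] = 1.0
                entries.append(LatticeEntry(Genome.from_array(vec), "single", subset))
                continue
            for comp in _compositions(steps, k):
                vec = np.zeros(4)
                for i, units in zip(subset_idx, comp):
                    vec[i] = units
                vec /= vec.sum()
                entries.append(
                    LatticeEntry(Genome.from_array(vec), _CLASS_NAMES[k], subset)
                )
    return LatticePlan(entries)


def run_lattice(
    plan: LatticePlan,
    arenas: dict[str, Arena],
    evaluator,
    repeats: int = 5,
    seed: int = 0,
    include_singles: bool = False,
) -> pd.DataFrame:
    """Evaluate every (formulation, arena, repeat) cell of the sweep.

    Returns one row per experiment; with the 282 multi-oil formulations, one
    arena and 5 repeats this is the 1410-video campaign.
    """
    entries = plan.formulations if include_singles else plan.multi_oil()
    rows = []
    for e_i, entry in enumerate(entries):
        for a_i, (arena_id, arena) in enumerate(arenas.items()):
            cell_ss = np.random.SeedSequence([seed, e_i, a_i])
            rep_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in cell_ss.spawn(repeats)
            ]
            for r, s in enumerate(rep_seeds):
                row = {
                    "subset": "+".join(entry.subset),
                    "class": entry.label,
                    "arena": arena_id,
                    "repeat": r,
                    "seed": s,
                    "fitness": float(evaluator(entry.genome, arena, s)),
                }
                row.update(entry.genome.to_dict())
                rows.append(row)
    return pd.DataFrame(rows)
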