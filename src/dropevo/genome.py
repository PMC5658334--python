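"""Formulation genomes and genetic-algorithm variation/selection operators.

A genome is a point on the 4-component mixture simplex: the volume fractions
of 1-octanol, diethyl phthalate (DEP), octanoic acid and 1-pentanol that make
up a droplet recipe. Fractions are non-negative and sum to one.

The operators here are the classic GA toolbox specialised to the simplex:
uniform random initialisation (flat Dirichlet), one-point crossover followed
by renormalisation, additive Gaussian mutation with clamping, and
fitness-proportionate (roulette-wheel) selection without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OILS",
    "Genome",
    "Individual",
    "random_genome",
    "normalize",
    "one_point_crossover",
    "gaussian_mutation",
    "roulette_select",
]

#: Canonical oil order used everywhere (CSV columns, genome vectors).
OILS = ("octanol", "dep", "octanoic", "pentanol")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Genome:
    """A droplet recipe: fractions of the four oils, summing to 1."""

    octanol: float
    dep: float
    octanoic: float
    pentanol: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < 0):
            raise ValueError(f"genome components must be non-negative, got {tuple(v)}")
        if abs(float(v.sum()) - 1.0) > _SUM_TOL:
            raise ValueError(f"genome components must sum to 1, got sum={v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.octanol, self.dep, self.octanoic, self.pentanol], dtype=float)

    @classmethod
    def from_array(cls, v) -> "Genome":
        v = np.asarray(v, dtype=float)
        if v.shape != (4,):
            raise ValueError(f"expected 4 components, got shape {v.shape}")
        return cls(*(float(x) for x in v))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in OILS}

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(**{k: float(d[k]) for k in OILS})


@dataclass
class Individual:
    """A genome together with its repeated fitness measurements."""

    genome: Genome
    repeat_fitnesses: list[float] = field(default_factory=list)

    @property
    def mean_fitness(self) -> float:
        if not self.repeat_fitnesses:
            raise ValueError("individual has not been evaluated")
        return float(np.mean(self.repeat_fitnesses))


def random_genome(rng: np.random.Generator) -> Genome:
    """Draw a genome uniformly from the simplex (flat Dirichlet).

    Uses the sorted-uniform-spacings construction, which is exactly the
    symmetric Dirichlet(1,1,1,1) distribution: each component has mean 1/4.
    """
    cuts = np.sort(rng.random(3))
    bounds = np.concatenate(([0.0], cuts, [1.0]))
    return Genome.from_array(np.diff(bounds))


def normalize(raw) -> Genome:
    """Scale four non-negative components so they sum to 1.

    Raises ``ValueError`` on an all-zero recipe (nothing to normalise).
    """
    v = np.asarray(raw, dtype=float)
    if v.shape != (4,):
        raise ValueError(f"expected 4 components, got shape {v.shape}")
    if np.any(v < 0):
        raise ValueError("components must be non-negative")
    s = float(v.sum())
    if s <= 0.0:
        raise ValueError("degenerate recipe: all components are zero")
    return Genome.from_array(v / s)


def one_point_crossover(a: Genome, b: Genome, rng: np.random.Generator) -> Genome:
    """One-point crossover of two recipes, renormalised to the simplex.

    The cut point k is uniform on the interior positions {1, 2, 3}; the child
    takes components [0, k) from ``a`` and [k, 4) from ``b``. Boundary cuts
    (0 or 4) would merely clone a parent and are excluded. If the chosen cut
    combines only zero components (possible when parents sit on the simplex
    boundary) the other cuts are tried; failing all, parent ``a`` is cloned.
    """
    va, vb = a.as_array(), b.as_array()
    cuts = [1, 2, 3]
    k = int(rng.integers(1, 4))
    cuts.remove(k)
    for cut in [k, *cuts]:
        child = np.concatenate([va[:cut], vb[cut:]])
        if child.sum() > 0:
            return normalize(child)
    return a


def gaussian_mutation(
    g: Genome, rng: np.random.Generator, variance: float = 0.1
) -> Genome:
    """Additive Gaussian mutation (mean 0, the given variance, default 0.1).

    Noise is added per component, negative components are clamped to zero and
    the result is renormalised. In the measure-zero event that clamping kills
    every component the noise is resampled.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return g
    base = g.as_array()
    sd = np.sqrt(variance)
    while True:
        mutated = np.clip(base + rng.normal(0.0, sd, size=4), 0.0, None)
        if mutated.sum() > 0:
            return normalize(mutated)


def roulette_select(
    population: list[Individual], k: int, rng: np.random.Generator
) -> list[Individual]:
    """Fitness-proportionate selection of ``k`` distinct individuals.

    Sequential sampling without replacement: each draw picks among the
    remaining candidates with probability proportional to mean fitness. If
    every remaining candidate has zero fitness the draw falls back to uniform.
    """
    if not population:
        raise ValueError("population is empty")
    if not 0 < k <= len(population):
        raise ValueError(f"k={k} out of range for population of {len(population)}")
    remaining = list(range(len(population)))
    chosen: list[Individual] = []
    for _ in range(k):
        weights = np.array([population[i].mean_fitness for i in remaining], dtype=float)
        total = weights.sum()
        if total <= 0.0:
            probs = np.full(len(remaining), 1.0 / len(remaining))
        else:
            probs = weights / total
        idx = int(rng.choice(len(remaining), p=probs))
        chosen.append(population[remaining.pop(idx)])
    return chosen
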