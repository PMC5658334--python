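"""Programmable droplet arenas: empty dish, pillar grid, and L-system caves.

An arena is a circular dish (the camera sees it top-down) optionally filled
with cylindrical pillar obstacles of 2 mm diameter. Three families are used:

* ``empty`` — just the circular boundary;
* ``pillars`` — pillars on a square grid with 3 mm centre spacing;
* ``lsystem:<seed>`` — pillars dropped along the turtle walk of a stochastic
  Lindenmayer system, producing cave-like obstacle patterns.

Everything is 2D in millimetres; :func:`rasterize` bridges the geometry to
pixel grids for the simulator's renderer and collision tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "Arena",
    "LSystemSpec",
    "DEFAULT_ARENA_RADIUS_MM",
    "PILLAR_DIAMETER_MM",
    "PILLAR_SPACING_MM",
    "make_empty_arena",
    "make_pillar_arena",
    "make_lsystem_arena",
    "expand_lsystem",
    "interpret_lsystem",
    "rasterize",
]

# The dish radius is not a published constant; 27.5 mm maps the 275 px camera
# ROI at 10 px/mm and is the package default, overridable everywhere.
DEFAULT_ARENA_RADIUS_MM = 27.5
PILLAR_DIAMETER_MM = 2.0
PILLAR_SPACING_MM = 3.0


@dataclass(frozen=True)
class Arena:
    """Circular arena with circular pillar obstacles (all lengths in mm)."""

    radius: float
    pillars: tuple[tuple[tuple[float, float], float], ...] = ()
    label: str = "empty"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")
        for (cx, cy), d in self.pillars:
            if d <= 0:
                raise ValueError("pillar diameter must be positive")
            if np.hypot(cx, cy) > self.radius:
                raise ValueError(f"pillar centre ({cx}, {cy}) outside the boundary")

    @property
    def n_pillars(self) -> int:
        return len(self.pillars)

    @cached_property
    def _pillar_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pillars:
            return np.empty((0, 2)), np.empty(0)
        centers = np.array([c for c, _ in self.pillars], dtype=float)
        radii = np.array([d / 2 for _, d in self.pillars], dtype=float)
        return centers, radii

    def pillar_centers(self) -> np.ndarray:
        return self._pillar_arrays[0]

    def pillar_radii(self) -> np.ndarray:
        return self._pillar_arrays[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "radius": self.radius,
                "label": self.label,
                "pillars": [
                    {"center": [cx, cy], "diameter": d} for (cx, cy), d in self.pillars
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "Arena":
        d = json.loads(s)
        pillars = tuple(
            ((p["center"][0], p["center"][1]), p["diameter"]) for p in d["pillars"]
        )
        return cls(radius=d["radius"], pillars=pillars, label=d["label"])


def make_empty_arena(radius: float = DEFAULT_ARENA_RADIUS_MM) -> Arena:
    """The obstacle-free dish — the first evolutionary environment."""
    return Arena(radius=radius, pillars=(), label="empty")


def make_pillar_arena(
    radius: float = DEFAULT_ARENA_RADIUS_MM,
    spacing: float = PILLAR_SPACING_MM,
    diameter: float = PILLAR_DIAMETER_MM,
) -> Arena:
    """Square grid of pillars, centres ``spacing`` mm apart, centred on the dish.

    Only pillars lying fully inside the boundary are kept, so every grid
    pillar has its four cardinal neighbours where the boundary allows.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing <= diameter:
        warnings.warn("pillar spacing <= diameter: pillars touch or overlap")
    n = int(np.floor(radius / spacing)) + 1
    pillars = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            cx, cy = i * spacing, j * spacing
            if np.hypot(cx, cy) + diameter / 2 <= radius:
                pillars.append(((cx, cy), diameter))
    return Arena(radius=radius, pillars=tuple(pillars), label="pillars")


@dataclass(frozen=True)
class LSystemSpec:
    """Stochastic Lindenmayer system plus turtle-interpretation parameters.

    ``rules`` maps a symbol to a list of (probability, expansion) choices;
    per-symbol probabilities must sum to 1. Symbols without rules are
    constants. The turtle reads F (step forward and drop a pillar), + / -
    (turn by ``turn_angle``), and [ ] (push/pop state, i.e. branching).
    """

    axiom: str = "F"
    rules: dict = field(
        default_factory=lambda: {"F": [(0.5, "F[+F]F"), (0.5, "F[-F]")]}
    )
    iterations: int = 4
    step_length: float = 3.0
    turn_angle: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sym, choices in self.rules.items():
            total = sum(p for p, _ in choices)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rule probabilities for {sym!r} sum to {total}, not 1")


_MAX_SYMBOLS = 200_000


def expand_lsystem(spec: LSystemSpec) -> str:
    """Rewrite the axiom in parallel for ``spec.iterations`` rounds.

    Stochastic rules are resolved with a generator seeded from ``spec.seed``,
    so the same spec always yields the same string. Growth beyond a symbol
    cap raises instead of exhausting memory.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.axiom
    for _ in range(spec.iterations):
        out = []
        for ch in s:
            choices = spec.rules.get(ch)
            if choices is None:
                out.append(ch)
            elif len(choices) == 1:
                out.append(choices[0][1])
            else:
                probs = [p for p, _ in choices]
                idx = int(rng.choice(len(choices), p=probs))
                out.append(choices[idx][1])
        s = "".join(out)
        if len(s) > _MAX_SYMBOLS:
            raise ValueError(f"L-system expansion exceeded {_MAX_SYMBOLS} symbols")
    return s


def interpret_lsystem(
    s: str,
    spec: LSystemSpec,
    arena_radius: float = DEFAULT_ARENA_RADIUS_MM,
    pillar_diameter: float = PILLAR_DIAMETER_MM,
) -> Arena:
    """Turtle-walk the symbol string, dropping a pillar at the end of each F step.

    The walk starts at the arena centre heading north. Pillars that would
    poke outside the boundary or overlap an already placed pillar are
    discarded (physical pillars cannot interpenetrate). Unmatched brackets
    raise ``ValueError``.
    """
    x, y = 0.0, 0.0
    heading = np.deg2rad(90.0)
    stack: list[tuple[float, float, float]] = []
    centers: list[tuple[float, float]] = []
    r_p = pillar_diameter / 2
    for ch in s:
        if ch == "F":
            x += spec.step_length * np.cos(heading)
            y += spec.step_length * np.sin(heading)
            if np.hypot(x, y) + r_p <= arena_radius and all(
                np.hypot(x - px, y - py) >= pillar_diameter for px, py in centers
            ):
                centers.append((x, y))
        elif ch == "+":
            heading += np.deg2rad(spec.turn_angle)
        elif ch == "-":
            heading -= np.deg2rad(spec.turn_angle)
        elif ch == "[":
            stack.append((x, y, heading))
        elif ch == "]":
            if not stack:
                raise ValueError("unmatched ']' in L-system string")
            x, y, heading = stack.pop()
        # other symbols are no-ops for the turtle
    if stack:
        raise ValueError("unmatched '[' in L-system string")
    pillars = tuple(((cx, cy), pillar_diameter) for cx, cy in centers)
    return Arena(radius=arena_radius, pillars=pillars, label=f"lsystem:{spec.seed}")


def make_lsystem_arena(
    seed: int = 7,
    radius: float = DEFAULT_ARENA_RADIUS_MM,
    spec: LSystemSpec | None = None,
) -> Arena:
    """Expand and interpret a (default) stochastic L-system into a cave arena."""
    if spec is None:
        spec = LSystemSpec(seed=seed)
    elif spec.seed != seed:
        spec = LSystemSpec(
            axiom=spec.axiom,
            rules=spec.rules,
            iterations=spec.iterations,
            step_length=spec.step_length,
            turn_angle=spec.turn_angle,
            seed=seed,
        )
    return interpret_lsystem(expand_lsystem(spec), spec, arena_radius=radius)


def rasterize(a: Arena, px_per_mm: float, shape: tuple[int, int] | None = None):
    """Boolean occupancy grids at the given resolution.

    Returns ``(occupied, inside)``: ``occupied`` marks pillar interiors,
    ``inside`` marks the dish interior. With no ``shape`` the grid tightly
    covers the dish; otherwise the dish is centred in the given (rows, cols).
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    if shape is None:
        n = int(np.ceil(2 * a.radius * px_per_mm))
        shape = (n, n)
    rows, cols = shape
    cy0, cx0 = (rows - 1) / 2, (cols - 1) / 2
    yy, xx = np.mgrid[0:rows, 0:cols]
    wx = (xx - cx0) / px_per_mm
    wy = (yy - cy0) / px_per_mm
    inside = wx**2 + wy**2 <= a.radius**2
    occupied = np.zeros(shape, dtype=bool)
    for (px, py), d in a.pillars:
        occupied |= (wx - px) ** 2 + (wy - py) ** 2 <= (d / 2) ** 2
    return occupied, inside
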