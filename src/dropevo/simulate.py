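"""Phenomenological simulator for self-propelled oil droplets in an arena.

The physical system — oil-mix droplets whose Marangoni-driven motion, division
and dissolution depend on the oil ratios — has no tractable first-principles
model, so this module is an explicit phenomenological stand-in: an
active-Brownian-particle model whose behavioural coefficients are a smooth
function of the formulation genome. It produces both ground-truth agent
trajectories and rendered 800x600 grayscale video frames, emulating the
camera view the vision pipeline consumes.

Model sketch (all lengths mm, times s):

* each droplet moves at a genome-dependent speed with rotational diffusion
  until its "fuel" (surfactant/solubility budget) runs out, after which
  propulsion shuts down within a couple of seconds; higher-motility recipes
  carry more fuel, so they keep moving longer;
* droplets reflect specularly off the dish boundary and off pillars;
* an energetic pillar impact can split a droplet into two half-volume
  daughters (probability grows with the division-rate trait);
* pillars can hook passing droplets (probability grows with the attraction
  trait); hooked droplets sit still and either unhook after an exponential
  holding time (faster for stable recipes) or become permanently trapped;
* trapped low-stability droplets dissolve and disappear.

The genome-to-trait map direction is anchored to the observed chemistry:
pentanol and octanol (high water solubility) drive motility, DEP (dense,
viscous) suppresses it, octanoic acid promotes division and pillar affinity,
and pentanol excess destabilises droplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .arena import Arena
from .genome import Genome

__all__ = [
    "TraitVector",
    "DropletAgent",
    "SimConfig",
    "SimResult",
    "DEFAULT_TRAIT_PARAMS",
    "genome_to_traits",
    "step",
    "simulate_experiment",
    "render_frame",
    "render_frames",
    "MOVING",
    "HOOKED",
    "TRAPPED",
    "DISSOLVED",
]

MOVING, HOOKED, TRAPPED, DISSOLVED = "moving", "hooked", "trapped", "dissolved"

#: Grayscale intensities of the rendered scene (8-bit).
INTENSITY_OUTSIDE = 20
INTENSITY_DISH = 70
INTENSITY_PILLAR = 120
INTENSITY_DROPLET = 210

#: Droplet lens height used to map volume (ul == mm^3) to a visible radius.
LENS_HEIGHT_MM = 1.0

#: Window after which a non-moving droplet no longer counts as active.
ACTIVITY_WINDOW_S = 3.0

# Behavioural coefficients of the genome->trait map and the dynamics. These
# are the module's tunable phenomenology; defaults give mm/s-scale speeds and
# make the three arenas select for visibly different recipes.
DEFAULT_TRAIT_PARAMS: dict[str, float] = {
    "motility_max": 3.0,        # mm/s at full activation
    "w_pentanol": 1.0,          # solubility-driven Marangoni activation
    "w_octanol": 0.7,
    "w_octanoic": 0.2,
    "dep_damping": 1.0,         # dense/viscous DEP suppresses propulsion
    "div_octanoic": 0.5,        # 1/s contribution of octanoic acid
    "div_motility": 0.15,       # fast droplets split more readily on impact
    "stab_pentanol": 0.8,       # pentanol excess destabilises the droplet
    "attr_base": 0.10,          # pillar affinity of any droplet
    "attr_octanoic": 0.8,
    "attr_dep": 0.3,
    "decay_base": 0.01,         # 1/s dissolution floor for trapped droplets
    "decay_instability": 0.10,
    # dynamics
    "rot_diffusion": 0.5,       # rad^2/s
    "lifetime_scale": 180.0,    # s of fuel at full motility (scales linearly)
    "lifetime_off_tau": 1.5,    # s, propulsion shutdown time once fuel is out
    "speed_mult_sigma": 0.35,   # lognormal per-droplet motility spread
    "static_speed": 0.1,        # mm/s, below this a droplet is "not moving"
    "speed_ema_alpha": 0.1,     # smoothing of the measured speed per step
    "split_speed": 0.8,         # mm/s impact speed needed to split
    "split_gain": 0.8,          # impact split prob = div_rate * gain
    "min_split_volume": 6.0,    # ul, below this droplets no longer split
    "hook_gain": 1.0,           # impact hook prob = attraction * gain
    "hold_base": 5.0,           # s, mean hooked holding time scale
    "trap_rate": 0.30,          # 1/s * (1-stability) while hooked
    "max_agents": 40,
}


@dataclass(frozen=True)
class TraitVector:
    """Behavioural phenotype of a recipe."""

    motility: float       # mm/s
    division_rate: float  # 1/s
    stability: float      # [0, 1]
    attraction: float     # [0, 1]
    decay_rate: float     # 1/s

    def __post_init__(self) -> None:
        if min(self.motility, self.division_rate, self.decay_rate) < 0:
            raise ValueError("traits must be non-negative")
        if not (0 <= self.stability <= 1 and 0 <= self.attraction <= 1):
            raise ValueError("stability and attraction must lie in [0, 1]")


def genome_to_traits(g: Genome, params: dict | None = None) -> TraitVector:
    """Map a formulation genome to behavioural traits (smooth, deterministic)."""
    p = dict(DEFAULT_TRAIT_PARAMS)
    if params:
        p.update(params)
    act = (
        p["w_pentanol"] * g.pentanol
        + p["w_octanol"] * g.octanol
        + p["w_octanoic"] * g.octanoic
    )
    motility = p["motility_max"] * act * max(0.0, 1.0 - p["dep_damping"] * g.dep)
    division = p["div_octanoic"] * g.octanoic + p["div_motility"] * motility / max(
        p["motility_max"], 1e-12
    )
    stability = min(1.0, max(0.0, 1.0 - p["stab_pentanol"] * g.pentanol))
    attraction = min(
        1.0, p["attr_base"] + p["attr_octanoic"] * g.octanoic + p["attr_dep"] * g.dep
    )
    decay = p["decay_base"] + p["decay_instability"] * (1.0 - stability)
    return TraitVector(motility, division, stability, attraction, decay)


def volume_to_radius(volume_ul: float) -> float:
    """Radius of the droplet lens seen from above (fixed-height lens model)."""
    return math.sqrt(volume_ul / (math.pi * LENS_HEIGHT_MM))


@dataclass
class DropletAgent:
    """One droplet in the simulation (positions in mm, dish-centred frame)."""

    x: float
    y: float
    heading: float          # rad
    volume: float           # ul
    speed_mult: float = 1.0
    state: str = MOVING
    static_time: float = 0.0
    hook_timer: float = 0.0
    avg_speed: float = 1.0  # smoothed measured speed, mm/s; fresh droplets count as moving
    lifetime: float = math.inf  # s of propulsion before fuel runs out
    radius: float = 0.0     # mm, derived from volume (lens model)

    def __post_init__(self) -> None:
        self.radius = volume_to_radius(self.volume) if self.volume > 0 else 0.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SimConfig:
    """Experiment configuration mirroring the physical protocol."""

    n_droplets: int = 5
    droplet_volume: float = 10.0   # ul
    duration: float = 60.0         # s
    fps: int = 30
    noise_amplitude: float = 0.01  # mm/sqrt(s) translational jitter
    px_per_mm: float = 10.0
    frame_shape: tuple[int, int] = (600, 800)
    trait_params: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


FrameSnapshot = list[tuple[float, float, float, str]]  # (x, y, radius, state)


@dataclass
class SimResult:
    """Trajectory plus per-frame ground-truth active-droplet counts."""

    frames: list[FrameSnapshot]
    active_counts: np.ndarray
    arena: Arena
    config: SimConfig

    @property
    def final_active_count(self) -> int:
        return int(self.active_counts[-1])


def _snapshot(agents: list[DropletAgent]) -> FrameSnapshot:
    return [
        (a.x, a.y, a.radius, a.state) for a in agents if a.state != DISSOLVED
    ]


def _active_count(agents: list[DropletAgent]) -> int:
    return sum(
        1
        for a in agents
        if a.state != DISSOLVED and a.static_time <= ACTIVITY_WINDOW_S
    )


def step(
    agents: list[DropletAgent],
    arena: Arena,
    traits: TraitVector,
    dt: float,
    rng: np.random.Generator,
    params: dict | None = None,
    t: float = 0.0,
    noise_amplitude: float = 0.01,
    pillar_tree: cKDTree | None = None,
) -> list[DropletAgent]:
    """Advance every agent by ``dt`` seconds; returns the (possibly grown) list.

    Splits append daughters, dissolution flips state; total droplet volume is
    conserved by splits and only removed by dissolution.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = dict(DEFAULT_TRAIT_PARAMS)
    if params:
        p.update(params)
    if pillar_tree is None and arena.n_pillars:
        pillar_tree = cKDTree(arena.pillar_centers())
    pillar_r = arena.pillar_radii()
    centers = arena.pillar_centers()

    sqrt_dt = math.sqrt(dt)
    new_agents: list[DropletAgent] = []

    # -- immobile states first: trapped may dissolve, hooked may unhook/trap
    for a in agents:
        if a.state == TRAPPED:
            a.static_time += dt
            if rng.random() < traits.decay_rate * dt:
                a.state = DISSOLVED
                a.static_time = 0.0
        elif a.state == HOOKED:
            a.static_time += dt
            a.hook_timer -= dt
            if rng.random() < p["trap_rate"] * (1.0 - traits.stability) * dt:
                a.state = TRAPPED
            elif a.hook_timer <= 0:
                a.state = MOVING
                a.heading = rng.uniform(0, 2 * math.pi)
                a.avg_speed = 1.0

    movers = [a for a in agents if a.state == MOVING]
    if movers:
        n = len(movers)
        x = np.array([a.x for a in movers])
        y = np.array([a.y for a in movers])
        heading = np.array([a.heading for a in movers])
        mult = np.array([a.speed_mult for a in movers])
        r = np.array([a.radius for a in movers])

        # active Brownian update: rotational diffusion + propulsion + jitter;
        # propulsion shuts down exponentially once a droplet's fuel is spent
        lifetime = np.array([a.lifetime for a in movers])
        spent = np.clip(t - lifetime, 0.0, None)
        speed_scale = np.exp(-spent / p["lifetime_off_tau"])
        heading = heading + math.sqrt(2 * p["rot_diffusion"] * dt) * rng.standard_normal(n)
        speed = traits.motility * mult * speed_scale
        jitter = noise_amplitude * sqrt_dt * rng.standard_normal((2, n))
        nx = x + speed * np.cos(heading) * dt + jitter[0]
        ny = y + speed * np.sin(heading) * dt + jitter[1]

        # dish boundary: clamp to the rim and reflect the heading
        d_c = np.hypot(nx, ny)
        limit = arena.radius - r
        over = d_c > limit
        if np.any(over):
            ux, uy = nx[over] / d_c[over], ny[over] / d_c[over]
            nx[over], ny[over] = ux * limit[over], uy * limit[over]
            hx, hy = np.cos(heading[over]), np.sin(heading[over])
            dot = hx * ux + hy * uy
            heading[over] = np.arctan2(hy - 2 * dot * uy, hx - 2 * dot * ux)

        # nearest pillar per agent, one batched query per step
        if pillar_tree is not None and len(centers):
            dist, jn = pillar_tree.query(np.column_stack([nx, ny]))
            contact = dist < pillar_r[jn] + r
        else:
            contact = np.zeros(n, dtype=bool)

        for i, a in enumerate(movers):
            a.heading = float(heading[i])
            xi, yi = float(nx[i]), float(ny[i])
            if contact[i]:
                j = int(jn[i])
                px, py = centers[j]
                touch = pillar_r[j] + a.radius
                di = float(dist[i])
                if di > 1e-12:
                    ux, uy = (xi - px) / di, (yi - py) / di
                else:
                    ux, uy = -math.cos(a.heading), -math.sin(a.heading)
                xi, yi = px + ux * touch, py + uy * touch
                if (
                    float(speed[i]) > p["split_speed"]
                    and a.volume >= p["min_split_volume"]
                    and len(agents) + len(new_agents) < p["max_agents"]
                    and rng.random() < min(1.0, traits.division_rate * p["split_gain"])
                ):
                    # split: two half-volume daughters leave tangentially
                    tx, ty = -uy, ux
                    half = a.volume / 2.0
                    r_h = volume_to_radius(half)
                    for sgn in (+1.0, -1.0):
                        new_agents.append(
                            DropletAgent(
                                x=px + ux * (touch + 0.2) + sgn * tx * (r_h + 0.1),
                                y=py + uy * (touch + 0.2) + sgn * ty * (r_h + 0.1),
                                heading=math.atan2(sgn * ty + uy, sgn * tx + ux),
                                volume=half,
                                speed_mult=a.speed_mult,
                                lifetime=a.lifetime,
                            )
                        )
                    a.state = DISSOLVED  # replaced by daughters; volume conserved
                    a.volume = 0.0
                    continue
                if rng.random() < min(1.0, traits.attraction * p["hook_gain"]):
                    a.state = HOOKED
                    hold = p["hold_base"] * (1.5 - traits.stability)
                    a.hook_timer = rng.exponential(hold)
                    a.x, a.y = xi, yi
                    continue
                # specular bounce off the pillar
                hx, hy = math.cos(a.heading), math.sin(a.heading)
                dot = hx * ux + hy * uy
                if dot < 0:
                    a.heading = math.atan2(hy - 2 * dot * uy, hx - 2 * dot * ux)

            # static detection on a smoothed speed so frame-level jitter does
            # not keep a dead droplet "moving"
            moved = math.hypot(xi - a.x, yi - a.y)
            alpha = p["speed_ema_alpha"]
            a.avg_speed = (1 - alpha) * a.avg_speed + alpha * moved / dt
            if a.avg_speed < p["static_speed"]:
                a.static_time += dt
            else:
                a.static_time = 0.0
            a.x, a.y = xi, yi

    agents.extend(new_agents)

    # soft droplet-droplet repulsion: surfactant shells keep droplets from
    # coalescing, so enforce a small standoff between surfaces
    shell = 0.3  # mm
    live = [a for a in agents if a.state == MOVING]
    for i in range(len(live)):
        for k in range(i + 1, len(live)):
            b, c = live[i], live[k]
            dx, dy = c.x - b.x, c.y - b.y
            d = math.hypot(dx, dy)
            overlap = b.radius + c.radius + shell - d
            if overlap > 0 and d > 1e-9:
                ux, uy = dx / d, dy / d
                push = overlap / 2
                b.x -= push * ux
                b.y -= push * uy
                c.x += push * ux
                c.y += push * uy
                # scatter: reflect each heading off the contact normal so
                # colliding droplets separate instead of drifting as a pair
                hbx, hby = math.cos(b.heading), math.sin(b.heading)
                dot = hbx * ux + hby * uy
                if dot > 0:
                    b.heading = math.atan2(hby - 2 * dot * uy, hbx - 2 * dot * ux)
                hcx, hcy = math.cos(c.heading), math.sin(c.heading)
                dot = -(hcx * ux + hcy * uy)
                if dot > 0:
                    c.heading = math.atan2(hcy + 2 * dot * uy, hcx + 2 * dot * ux)
    return agents


def _inject(
    cfg: SimConfig, arena: Arena, traits: TraitVector, rng: np.random.Generator
) -> list[DropletAgent]:
    """Place the initial droplets near the inlet at the bottom of the dish.

    Each droplet draws a lognormal motility multiplier and a fuel lifetime
    proportional to the recipe's motility — faster recipes keep moving
    longer, which is what the final-frame fitness rewards.
    """
    p = dict(DEFAULT_TRAIT_PARAMS)
    p.update(cfg.trait_params)
    r = volume_to_radius(cfg.droplet_volume)
    base_y = -(arena.radius - 3.0 * r)
    agents = []
    for i in range(cfg.n_droplets):
        mult = float(rng.lognormal(0.0, p["speed_mult_sigma"]))
        lifetime = p["lifetime_scale"] * (traits.motility / p["motility_max"]) * mult
        agents.append(
            DropletAgent(
                x=(i - (cfg.n_droplets - 1) / 2) * 2.2 * r + rng.normal(0, 0.2),
                y=base_y + rng.normal(0, 0.2),
                heading=rng.uniform(0, 2 * math.pi),
                volume=cfg.droplet_volume,
                speed_mult=mult,
                lifetime=lifetime,
            )
        )
    return agents


def simulate_experiment(
    g: Genome, arena: Arena, cfg: SimConfig | None = None, seed: int = 0
) -> SimResult:
    """Run one full experiment: inject droplets, step for duration x fps frames.

    Returns the per-frame snapshots and the ground-truth count of droplets
    that moved within the trailing 3 s window ("active" droplets) — the
    quantity the vision pipeline is meant to recover.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = dict(DEFAULT_TRAIT_PARAMS)
    p.update(cfg.trait_params)
    traits = genome_to_traits(g, cfg.trait_params)
    agents = _inject(cfg, arena, traits, rng)
    tree = cKDTree(arena.pillar_centers()) if arena.n_pillars else None

    frames: list[FrameSnapshot] = []
    counts = np.zeros(cfg.n_frames, dtype=int)
    dt = cfg.dt
    for f in range(cfg.n_frames):
        frames.append(_snapshot(agents))
        counts[f] = _active_count(agents)
        step(
            agents,
            arena,
            traits,
            dt,
            rng,
            params=cfg.trait_params,
            t=f * dt,
            noise_amplitude=cfg.noise_amplitude,
            pillar_tree=tree,
        )
    return SimResult(frames=frames, active_counts=counts, arena=arena, config=cfg)


# ---------------------------------------------------------------------------
# rendering


@lru_cache(maxsize=8)
def _background(arena: Arena, px_per_mm: float, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    cy0, cx0 = (rows - 1) / 2, (cols - 1) / 2
    yy, xx = np.mgrid[0:rows, 0:cols]
    wx = (xx - cx0) / px_per_mm
    wy = (cy0 - yy) / px_per_mm  # image rows grow downwards; world y grows up
    img = np.full(shape, INTENSITY_OUTSIDE, dtype=np.uint8)
    img[wx**2 + wy**2 <= arena.radius**2] = INTENSITY_DISH
    for (px, py), d in arena.pillars:
        img[(wx - px) ** 2 + (wy - py) ** 2 <= (d / 2) ** 2] = INTENSITY_PILLAR
    return img


def _stamp_disc(img: np.ndarray, cx: float, cy: float, r: float, value: int) -> None:
    rows, cols = img.shape
    x0, x1 = max(0, int(cx - r) - 1), min(cols, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(rows, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1][(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value


def render_frame(
    agents: FrameSnapshot | list[DropletAgent],
    arena: Arena,
    px_per_mm: float = 10.0,
    shape: tuple[int, int] = (600, 800),
) -> np.ndarray:
    """Render one grayscale camera frame: static background plus droplet discs."""
    img = _background(arena, px_per_mm, shape).copy()
    rows, cols = shape
    cy0, cx0 = (rows - 1) / 2, (cols - 1) / 2
    for a in agents:
        if isinstance(a, DropletAgent):
            if a.state == DISSOLVED:
                continue
            x, y, r = a.x, a.y, a.radius
        else:
            x, y, r, state = a
            if state == DISSOLVED:
                continue
        _stamp_disc(img, cx0 + x * px_per_mm, cy0 - y * px_per_mm, r * px_per_mm, INTENSITY_DROPLET)
    return img


def render_frames(result: SimResult):
    """Generator over rendered frames of a finished simulation."""
    cfg = result.config
    for snap in result.frames:
        yield render_frame(snap, result.arena, cfg.px_per_mm, cfg.frame_shape)


def reduced_config(duration: float = 30.0, fps: int = 10, **kw) -> SimConfig:
    """A cheaper experiment profile for large simulation campaigns.

    Same physics, shorter observation window and coarser time step; used by
    the batch drivers when thousands of experiments are needed.
    """
    return SimConfig(duration=duration, fps=fps, **kw)
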