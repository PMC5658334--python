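"""Scripted synthetic videos with exact ground truth.

Unlike the physics simulator, these clips move droplet discs along fully
prescribed paths (circular orbits inside the dish), so the number of moving
droplets at any frame is known exactly. They are the controlled input for
validating the detector: "all droplets keep moving" or "droplet i stops at
t = t_i" can be stated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena, make_empty_arena
from .simulate import render_frame

__all__ = ["ScriptedVideo", "orbiting_droplets_video"]


@dataclass
class ScriptedVideo:
    """Frame generator plus the ground-truth moving count at the final frame."""

    n_frames: int
    fps: int
    arena: Arena
    paths: list          # per droplet: callable t -> (x, y) mm
    stop_times: list     # per droplet: time (s) it freezes, or None
    radius_mm: float
    px_per_mm: float = 10.0
    shape: tuple[int, int] = (600, 800)
    noise_sd: float = 0.0
    seed: int = 0

    def position(self, i: int, t: float) -> tuple[float, float]:
        stop = self.stop_times[i]
        if stop is not None and t >= stop:
            t = stop
        return self.paths[i](t)

    def frames(self):
        rng = np.random.default_rng(self.seed)
        for f in range(self.n_frames):
            t = f / self.fps
            snap = [
                (*self.position(i, t), self.radius_mm, "moving")
                for i in range(len(self.paths))
            ]
            img = render_frame(snap, self.arena, self.px_per_mm, self.shape)
            if self.noise_sd > 0:
                noisy = img.astype(np.float32) + rng.normal(0, self.noise_sd, img.shape)
                img = np.clip(noisy, 0, 255).astype(np.uint8)
            yield img

    def moving_count_at(self, frame_index: int) -> int:
        t = frame_index / self.fps
        return sum(
            1
            for stop in self.stop_times
            if stop is None or t < stop + 3.0  # 3 s trailing activity window
        )


def orbiting_droplets_video(
    n_droplets: int = 5,
    stop_times: list | None = None,
    duration: float = 60.0,
    fps: int = 30,
    arena: Arena | None = None,
    speed_mm_s: float = 3.0,
    radius_mm: float = 1.8,
    shape: tuple[int, int] = (600, 800),
    px_per_mm: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScriptedVideo:
    """Droplets orbiting the dish centre at distinct radii and phases.

    Orbit radii are spaced so the discs never touch; each droplet moves at
    ``speed_mm_s`` along its circle unless (and until) its stop time passes.
    """
    arena = arena or make_empty_arena()
    if stop_times is None:
        stop_times = [None] * n_droplets
    if len(stop_times) != n_droplets:
        raise ValueError("need one stop time (or None) per droplet")
    r_min, r_max = 4.0, arena.radius - 2 * radius_mm
    orbit_r = np.linspace(r_min, r_max, n_droplets)
    phases = np.linspace(0, 2 * np.pi, n_droplets, endpoint=False)

    def make_path(rr: float, phase: float):
        omega = speed_mm_s / rr
        return lambda t: (rr * np.cos(phase + omega * t), rr * np.sin(phase + omega * t))

    paths = [make_path(rr, ph) for rr, ph in zip(orbit_r, phases)]
    return ScriptedVideo(
        n_frames=int(round(duration * fps)),
        fps=fps,
        arena=arena,
        paths=paths,
        stop_times=list(stop_times),
        radius_mm=radius_mm,
        px_per_mm=px_per_mm,
        shape=shape,
        noise_sd=noise_sd,
        seed=seed,
    )
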