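"""Droplet simulator: trait mapping, dynamics, conservation, rendering."""

import math

import numpy as np
import pytest

from dropevo.arena import Arena, make_empty_arena
from dropevo.genome import Genome, random_genome
from dropevo.simulate import (
    DISSOLVED,
    INTENSITY_DROPLET,
    DropletAgent,
    SimConfig,
    TraitVector,
    genome_to_traits,
    render_frame,
    render_frames,
    simulate_experiment,
    step,
    volume_to_radius,
)


class TestTraitMap:
    def test_deterministic(self):
        g = Genome(0.1, 0.2, 0.3, 0.4)
        assert genome_to_traits(g) == genome_to_traits(g)

    def test_pure_dep_is_immotile(self):
        traits = genome_to_traits(Genome(0, 1, 0, 0))
        assert traits.motility < 0.1  # below the moving-detection threshold

    def test_pentanol_drives_motility(self):
        fast = genome_to_traits(Genome(0, 0, 0, 1))
        slow = genome_to_traits(Genome(0, 0.5, 0, 0.5))
        assert fast.motility > slow.motility > 0

    def test_lipschitz_continuity(self, rng):
        # numeric check: trait distance bounded by a constant times genome distance
        L = 10.0
        for _ in range(200):
            g1, g2 = random_genome(rng), random_genome(rng)
            t1, t2 = genome_to_traits(g1), genome_to_traits(g2)
            dt = np.abs(
                [
                    t1.motility - t2.motility,
                    t1.division_rate - t2.division_rate,
                    t1.stability - t2.stability,
                    t1.attraction - t2.attraction,
                    t1.decay_rate - t2.decay_rate,
                ]
            ).max()
            dg = np.abs(g1.as_array() - g2.as_array()).sum()
            assert dt <= L * dg + 1e-12

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            TraitVector(-1, 0, 0.5, 0.5, 0)
        with pytest.raises(ValueError):
            TraitVector(1, 0, 1.5, 0.5, 0)


def immotile_traits():
    return TraitVector(motility=0.0, division_rate=0.0, stability=1.0, attraction=0.0, decay_rate=0.0)


class TestStep:
    def test_zero_motility_zero_noise_static(self, rng):
        arena = make_empty_arena()
        agents = [DropletAgent(x=3.0, y=-2.0, heading=0.4, volume=10.0)]
        for _ in range(100):
            step(agents, arena, immotile_traits(), 1 / 30, rng, noise_amplitude=0.0)
        assert agents[0].x == 3.0 and agents[0].y == -2.0

    def test_volume_non_increasing_and_split_conserving(self):
        # division-prone genome in a pillared arena: splits conserve volume
        from dropevo.arena import make_pillar_arena

        arena = make_pillar_arena(radius=15)
        g = Genome(0.3, 0.0, 0.4, 0.3)
        res = simulate_experiment(g, arena, SimConfig(duration=20, fps=20), seed=1)
        volumes = [
            sum(math.pi * r**2 for (_, _, r, s) in snap if s != DISSOLVED)
            for snap in res.frames
        ]
        assert any(len(snap) > 5 for snap in res.frames), "expected at least one split"
        for prev, cur in zip(volumes, volumes[1:]):
            assert cur <= prev + 1e-6

    def test_no_pillar_penetration_at_fine_dt(self, rng):
        arena = Arena(radius=15, pillars=(((0.0, 0.0), 2.0),), label="one")
        traits = TraitVector(motility=3.0, division_rate=0.0, stability=1.0, attraction=0.0, decay_rate=0.0)
        # aim straight at the pillar from the left
        agents = [DropletAgent(x=-6.0, y=0.0, heading=0.0, volume=10.0)]
        r_d = agents[0].radius
        min_gap = np.inf
        for _ in range(4000):
            step(agents, arena, traits, 1e-3, rng, params={"rot_diffusion": 0.0}, noise_amplitude=0.0)
            a = agents[0]
            min_gap = min(min_gap, math.hypot(a.x, a.y))
        assert min_gap >= 1.0 + r_d - 1e-6  # pillar radius + droplet radius

    def test_boundary_confinement(self, rng):
        arena = make_empty_arena(10.0)
        traits = TraitVector(motility=5.0, division_rate=0.0, stability=1.0, attraction=0.0, decay_rate=0.0)
        agents = [DropletAgent(x=0.0, y=0.0, heading=1.0, volume=10.0)]
        for _ in range(2000):
            step(agents, arena, traits, 1 / 30, rng)
        a = agents[0]
        assert math.hypot(a.x, a.y) <= 10.0 - a.radius + 1e-6


class TestSimulateExperiment:
    def test_frame_count_and_initial_droplets(self, arenas):
        res = simulate_experiment(Genome(0.25, 0.25, 0.25, 0.25), arenas["empty"], SimConfig(), seed=0)
        assert len(res.frames) == 1800
        assert res.active_counts[0] == 5
        assert len(res.frames[0]) == 5

    def test_same_seed_identical_trajectory(self, arenas):
        cfg = SimConfig(duration=10, fps=10)
        g = Genome(0.2, 0.1, 0.2, 0.5)
        r1 = simulate_experiment(g, arenas["pillars"], cfg, seed=5)
        r2 = simulate_experiment(g, arenas["pillars"], cfg, seed=5)
        assert r1.frames == r2.frames
        assert np.array_equal(r1.active_counts, r2.active_counts)

    def test_immotile_genome_goes_inactive(self, arenas):
        res = simulate_experiment(Genome(0, 1, 0, 0), arenas["empty"], SimConfig(duration=20, fps=10), seed=1)
        assert res.final_active_count == 0


class TestRender:
    def test_no_agents_is_background(self, arenas):
        f1 = render_frame([], arenas["pillars"])
        f2 = render_frame([], arenas["pillars"])
        assert np.array_equal(f1, f2)
        assert INTENSITY_DROPLET not in f1

    def test_droplet_blob_area(self, arenas):
        r = volume_to_radius(10.0)
        frame = render_frame([(0.0, 0.0, r, "moving")], arenas["empty"], px_per_mm=10.0)
        area = (frame == INTENSITY_DROPLET).sum()
        assert abs(area - math.pi * (10 * r) ** 2) / (math.pi * (10 * r) ** 2) < 0.1

    def test_pillar_pixels_static_across_frames(self, arenas):
        # pillars never move: a pillar pixel is either its fixed intensity or
        # momentarily occluded by a droplet drawn on top of it
        cfg = SimConfig(duration=2, fps=10)
        res = simulate_experiment(Genome(0.2, 0.1, 0.2, 0.5), arenas["pillars"], cfg, seed=2)
        pillar_mask = render_frame([], arenas["pillars"]) == 120
        for f in render_frames(res):
            vals = np.unique(f[pillar_mask])
            assert set(vals.tolist()) <= {120, INTENSITY_DROPLET}

    def test_dissolved_not_drawn(self, arenas):
        frame = render_frame([(0.0, 0.0, 1.8, DISSOLVED)], arenas["empty"])
        assert INTENSITY_DROPLET not in frame

    def test_full_video_byte_reproducible(self, arenas):
        cfg = SimConfig(duration=3, fps=10, px_per_mm=5.0, frame_shape=(300, 400))
        g = Genome(0.2, 0.1, 0.2, 0.5)
        v1 = np.stack(list(render_frames(simulate_experiment(g, arenas["pillars"], cfg, seed=9))))
        v2 = np.stack(list(render_frames(simulate_experiment(g, arenas["pillars"], cfg, seed=9))))
        assert np.array_equal(v1, v2)
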