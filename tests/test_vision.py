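"""Detector: ROI, background model, blob extraction, video fitness."""

import numpy as np
import pytest

from dropevo.arena import make_empty_arena
from dropevo.genome import Genome, random_genome
from dropevo.simulate import SimConfig, render_frames, simulate_experiment
from dropevo.synthetic import orbiting_droplets_video
from dropevo.vision import (
    MixtureBackgroundModel,
    VisionConfig,
    clean_mask,
    evaluate,
    find_droplets,
    fitness_from_video,
    roi_mask,
)

# reduced-scale profile used throughout: 138 px ROI on a 300x400 frame at
# 5 px/mm, 10 fps; history 30 frames keeps the 3 s background memory. The
# frames are noise-free, so speckle opening is off (it would erode the thin
# trailing crescents of slow droplets at this resolution).
SMALL_SHAPE = (300, 400)
SMALL_VCFG = VisionConfig(roi_radius=138, history_frames=30, min_area=10, open_radius=0)
SMALL_SIM = SimConfig(duration=20.0, fps=10, px_per_mm=5.0, frame_shape=SMALL_SHAPE)


def disc_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestRoiMask:
    def test_area_matches_disc(self):
        mask = roi_mask(VisionConfig(roi_radius=275), (600, 800))
        expected = np.pi * 275**2
        assert abs(mask.sum() - expected) / expected < 0.005

    def test_zero_radius_empty(self):
        assert roi_mask(VisionConfig(roi_radius=0), (100, 100)).sum() <= 1

    def test_reflection_symmetric(self):
        mask = roi_mask(VisionConfig(roi_radius=40), (100, 100))
        assert np.array_equal(mask, mask[::-1]) and np.array_equal(mask, mask[:, ::-1])


class TestBackgroundModel:
    def test_constant_video_no_foreground(self):
        cfg = VisionConfig(roi_radius=45, history_frames=30)
        model = MixtureBackgroundModel(cfg, (100, 100))
        frame = np.full((100, 100), 70, dtype=np.uint8)
        masks = [model.apply(frame) for _ in range(40)]
        assert not masks[-1].any()

    def test_moving_disc_overlaps_truth(self):
        cfg = VisionConfig(roi_radius=45, history_frames=30)
        model = MixtureBackgroundModel(cfg, (100, 100))
        for i in range(60):
            frame = np.full((100, 100), 70, dtype=np.uint8)
            cx = 20 + (2 * i) % 60  # two px per frame, fresh pixels every step
            frame[disc_mask((100, 100), cx, 50, 8)] = 210
            fg = model.apply(frame)
        truth = disc_mask((100, 100), 20 + (2 * 59) % 60, 50, 8) & model.mask
        inter = (fg & truth).sum()
        union = (fg | truth).sum()
        assert inter / union > 0.7

    def test_stopped_disc_absorbed_within_window(self):
        """A droplet frozen at t0 leaves the foreground 2-5 s later."""
        fps = 30
        v = orbiting_droplets_video(
            n_droplets=1, stop_times=[6.0], duration=14, fps=fps,
            shape=SMALL_SHAPE, px_per_mm=5,
        )
        cfg = VisionConfig(roi_radius=138, history_frames=90, min_area=10)
        model = None
        gone = None
        for i, frame in enumerate(v.frames()):
            if model is None:
                model = MixtureBackgroundModel(cfg, frame.shape)
            n = len(find_droplets(clean_mask(model.apply(frame), cfg.close_radius), cfg.min_area))
            t = i / fps
            if t > 6.0 and n == 0:
                gone = t
                break
        assert gone is not None, "stopped droplet never absorbed"
        assert 2.0 <= gone - 6.0 <= 5.0

    def test_frame_shape_mismatch(self):
        model = MixtureBackgroundModel(VisionConfig(roi_radius=10), (50, 50))
        with pytest.raises(ValueError):
            model.apply(np.zeros((60, 60), dtype=np.uint8))


class TestFindDroplets:
    def test_empty_mask(self):
        assert find_droplets(np.zeros((50, 50), dtype=bool)) == []

    def test_two_discs_centroids(self):
        mask = disc_mask((100, 100), 25, 30, 8) | disc_mask((100, 100), 70, 60, 8)
        dets = find_droplets(mask, min_area=10)
        assert len(dets) == 2
        centroids = sorted((round(d.centroid[0]), round(d.centroid[1])) for d in dets)
        assert abs(centroids[0][0] - 25) <= 1 and abs(centroids[0][1] - 30) <= 1
        assert abs(centroids[1][0] - 70) <= 1 and abs(centroids[1][1] - 60) <= 1

    def test_one_px_gap_separates_components(self):
        mask = disc_mask((60, 60), 30, 30, 10)
        mask[30, :] = False  # 1-px slit: separate even under 8-connectivity
        assert len(find_droplets(mask, min_area=10)) == 2

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # touch only at one diagonal corner
        assert len(find_droplets(mask, min_area=4)) == 1

    def test_min_area_filter(self):
        mask = disc_mask((50, 50), 25, 25, 2)
        assert find_droplets(mask, min_area=100) == []

    def test_contours_enclose_centroid(self):
        mask = disc_mask((60, 60), 30, 28, 9)
        (det,) = find_droplets(mask, min_area=10)
        assert len(det.contour) > 8
        assert np.allclose(det.contour.mean(axis=0), det.centroid, atol=2.0)


class TestFitnessFromVideo:
    def test_all_moving_returns_injection_count(self):
        v = orbiting_droplets_video(duration=20, fps=10, shape=SMALL_SHAPE, px_per_mm=5)
        assert fitness_from_video(v.frames(), SMALL_VCFG) == 5

    def test_one_stopped_droplet_not_counted(self):
        v = orbiting_droplets_video(
            stop_times=[8.0, None, None, None, None],
            duration=20, fps=10, shape=SMALL_SHAPE, px_per_mm=5,
        )
        assert fitness_from_video(v.frames(), SMALL_VCFG) == 4

    def test_all_stopped_is_zero(self):
        v = orbiting_droplets_video(
            stop_times=[5.0] * 5, duration=20, fps=10, shape=SMALL_SHAPE, px_per_mm=5
        )
        assert fitness_from_video(v.frames(), SMALL_VCFG) == 0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            fitness_from_video(iter(()))

    def test_robust_to_sensor_noise(self):
        # speckle opening on: the point of open_radius is exactly this case
        noisy_cfg = VisionConfig(roi_radius=138, history_frames=30, min_area=25, open_radius=1)
        v = orbiting_droplets_video(
            duration=20, fps=10, shape=SMALL_SHAPE, px_per_mm=5, noise_sd=2.0, seed=3
        )
        assert fitness_from_video(v.frames(), noisy_cfg) == 5


class TestEvaluate:
    def test_immotile_genome_scores_zero(self):
        f = evaluate(Genome(0, 1, 0, 0), make_empty_arena(), seed=0,
                     sim_config=SMALL_SIM, vision_config=SMALL_VCFG)
        assert f == 0.0

    def test_deterministic(self):
        g = Genome(0.2, 0.1, 0.2, 0.5)
        args = dict(sim_config=SMALL_SIM, vision_config=SMALL_VCFG)
        assert evaluate(g, make_empty_arena(), seed=4, **args) == evaluate(
            g, make_empty_arena(), seed=4, **args
        )

    def test_tracks_simulator_ground_truth(self):
        """Detected count stays within one droplet of the simulator's own
        trailing-3 s activity count for most random recipes (residual
        disagreement comes from touching droplets merging into one blob)."""
        arena = make_empty_arena()
        diffs = []
        for i in range(8):
            g = random_genome(np.random.default_rng(100 + i))
            res = simulate_experiment(g, arena, SMALL_SIM, seed=50 + i)
            f = fitness_from_video(render_frames(res), SMALL_VCFG)
            diffs.append(abs(f - res.final_active_count))
        assert np.mean(diffs) <= 1.0
        assert sum(d <= 1 for d in diffs) >= 6
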