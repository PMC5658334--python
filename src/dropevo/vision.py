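"""Droplet detection and the video fitness function.

The fitness of a droplet experiment is the number of droplets detected as
*moving* foreground in the final frame of its one-minute, 30 fps video. The
detector works inside a circular region of interest (radius 275 px, matching
the dish), classifies each pixel with an online mixture-of-Gaussians (MoG)
background model with a deliberately short memory — so any droplet that sits
still for roughly three seconds melts into the background and drops out of
the count — and extracts the remaining foreground blobs as droplets.

The MoG here is the classic Stauffer–Grimson adaptive mixture, implemented
vectorised over the ROI pixels: per pixel, K weighted Gaussians over
grayscale intensity, updated online with learning rate 1/history. A pixel is
background when its matched Gaussian has accumulated sufficient weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from skimage import measure, morphology

from .arena import Arena
from .genome import Genome

__all__ = [
    "VisionConfig",
    "DetectedDroplet",
    "MixtureBackgroundModel",
    "roi_mask",
    "find_droplets",
    "fitness_from_video",
    "evaluate",
    "VisionEvaluator",
    "ground_truth_evaluator",
]


@dataclass(frozen=True)
class VisionConfig:
    """Detector configuration.

    ``history_frames`` sets the background memory (90 frames = 3 s at
    30 fps); the learning rate defaults to its reciprocal, which calibrates
    the static-droplet absorption latency to the 2–3 s range the fitness
    definition relies on.
    """

    roi_center: tuple[int, int] | None = None  # (x, y) px; None = image centre
    roi_radius: int = 275
    history_frames: int = 90
    n_gaussians: int = 5
    match_threshold: float = 2.5        # in sigmas
    background_weight: float = 0.6      # matched weight above this = background
    initial_variance: float = 225.0     # sigma 15 grey levels
    min_variance: float = 4.0
    learning_rate: float | None = None  # None = 1 / history_frames
    min_area: float = 20.0              # px^2 blob filter
    open_radius: int = 1                # speckle removal before closing
    close_radius: int = 3               # morphological closing of the FG mask

    @property
    def lr(self) -> float:
        return self.learning_rate if self.learning_rate is not None else 1.0 / self.history_frames


@dataclass
class DetectedDroplet:
    centroid: tuple[float, float]  # (x, y) px
    area: float                    # px^2
    contour: np.ndarray            # (n, 2) boundary path in (x, y) px


def roi_mask(cfg: VisionConfig, shape: tuple[int, int]) -> np.ndarray:
    """Boolean disc mask: True inside the circular region of interest."""
    rows, cols = shape
    if cfg.roi_center is None:
        cx, cy = (cols - 1) / 2, (rows - 1) / 2
    else:
        cx, cy = cfg.roi_center
    yy, xx = np.mgrid[0:rows, 0:cols]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.roi_radius**2


class MixtureBackgroundModel:
    """Per-pixel adaptive Gaussian mixture over grayscale intensity.

    Restricted to the ROI pixels for speed; :meth:`apply` consumes one frame
    and returns the full-frame boolean foreground mask. The model must be
    re-created (reinitialised) for each experiment.
    """

    def __init__(self, cfg: VisionConfig, shape: tuple[int, int]):
        self.cfg = cfg
        self.shape = shape
        self.mask = roi_mask(cfg, shape)
        self._idx = np.flatnonzero(self.mask.ravel())
        n, k = self._idx.size, cfg.n_gaussians
        self.weights = np.zeros((k, n), dtype=np.float32)
        self.means = np.zeros((k, n), dtype=np.float32)
        self.variances = np.full((k, n), cfg.initial_variance, dtype=np.float32)
        self._initialised = False
        self.frames_seen = 0

    def apply(self, frame: np.ndarray) -> np.ndarray:
        if frame.shape != self.shape:
            raise ValueError(f"frame shape {frame.shape} != model shape {self.shape}")
        cfg = self.cfg
        x = frame.ravel()[self._idx].astype(np.float32)
        self.frames_seen += 1
        if not self._initialised:
            self.weights[0] = 1.0
            self.means[0] = x
            self._initialised = True
            return np.zeros(self.shape, dtype=bool)

        lr = cfg.lr
        w, mu, var = self.weights, self.means, self.variances
        d = x[None, :] - mu
        d2 = d * d
        matched = (d2 <= (cfg.match_threshold**2) * var) & (w > 0)

        # best-matching Gaussian per pixel: highest weight/sigma among matches
        score = np.where(matched, w / np.sqrt(var), -1.0)
        best = np.argmax(score, axis=0)
        cols = np.arange(x.size)
        any_match = matched[best, cols]

        # weight update: decay all, reinforce the matched winner
        w *= 1.0 - lr
        w[best[any_match], cols[any_match]] += lr

        # parameter update of the winner only
        bm, bc = best[any_match], cols[any_match]
        db = d[bm, bc]
        mu[bm, bc] += lr * db
        var[bm, bc] = np.maximum(
            var[bm, bc] + lr * (db * db - var[bm, bc]), cfg.min_variance
        )

        # unmatched pixels: replace the weakest Gaussian with a fresh one
        miss = cols[~any_match]
        if miss.size:
            weakest = np.argmin(w[:, miss], axis=0)
            w[weakest, miss] = lr
            mu[weakest, miss] = x[miss]
            var[weakest, miss] = cfg.initial_variance
            w[:, miss] /= w[:, miss].sum(axis=0)

        # foreground: no match, or the matched Gaussian is not yet background
        fg_roi = ~any_match | (w[best, cols] < cfg.background_weight)
        out = np.zeros(self.shape[0] * self.shape[1], dtype=bool)
        out[self._idx[fg_roi]] = True
        return out.reshape(self.shape)


def update_foreground(model: MixtureBackgroundModel, frame: np.ndarray) -> np.ndarray:
    """Functional alias: feed one frame through the model, get the FG mask."""
    return model.apply(frame)


def clean_mask(mask: np.ndarray, close_radius: int = 3, open_radius: int = 1) -> np.ndarray:
    """Morphological closing then opening of the foreground mask.

    Closing re-joins fragments of one droplet — a droplet moving slowly
    sheds its trailing pixels into the background, which can break its blob
    into crescents — without merging well-separated droplets. The opening
    afterwards removes isolated sensor-noise speckle, which closing leaves
    untouched but which would otherwise survive the area filter in clumps.
    """
    out = mask
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    if open_radius > 0:
        out = morphology.opening(out, morphology.disk(open_radius))
    return out.astype(bool)


def find_droplets(mask: np.ndarray, min_area: float = 20.0) -> list[DetectedDroplet]:
    """Extract droplets as 8-connected foreground components of sufficient area."""
    labels = measure.label(mask, connectivity=2)
    out: list[DetectedDroplet] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        # boundary contour traced on the filled component
        r0, c0, r1, c1 = region.bbox
        patch = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=float)
        patch[1:-1, 1:-1] = region.image_filled
        contours = measure.find_contours(patch, 0.5)
        if contours:
            path = max(contours, key=len)
            contour = np.column_stack(
                [path[:, 1] + c0 - 1, path[:, 0] + r0 - 1]
            )
        else:
            contour = np.empty((0, 2))
        out.append(DetectedDroplet(centroid=(cx, cy), area=float(region.area), contour=contour))
    return out


def fitness_from_video(
    frames: Iterable[np.ndarray], cfg: VisionConfig | None = None
) -> int:
    """Stream a video through a fresh MoG model; count droplets in the last frame.

    This is the experiment's fitness: the number of detected (still-moving)
    droplets at the final frame, nominally frame 1800 of a 60 s, 30 fps video.
    """
    cfg = cfg or VisionConfig()
    model: MixtureBackgroundModel | None = None
    last_mask: np.ndarray | None = None
    for frame in frames:
        if model is None:
            model = MixtureBackgroundModel(cfg, frame.shape)
        last_mask = model.apply(frame)
    if model is None or last_mask is None:
        raise ValueError("empty frame stream")
    return len(find_droplets(clean_mask(last_mask, cfg.close_radius, cfg.open_radius), cfg.min_area))


def per_frame_counts(
    frames: Iterable[np.ndarray], cfg: VisionConfig | None = None
) -> Iterator[int]:
    """Droplet count for every frame (debug/inspection aid)."""
    cfg = cfg or VisionConfig()
    model: MixtureBackgroundModel | None = None
    for frame in frames:
        if model is None:
            model = MixtureBackgroundModel(cfg, frame.shape)
        yield len(
            find_droplets(clean_mask(model.apply(frame), cfg.close_radius, cfg.open_radius), cfg.min_area)
        )


# ---------------------------------------------------------------------------
# evaluators: (genome, arena, seed) -> fitness


@dataclass
class VisionEvaluator:
    """Full-pipeline evaluator: simulate -> render -> detect.

    The callable form is what the GA driver injects as its fitness oracle.
    """

    sim_config: "object" = None    # SimConfig; None = defaults
    vision_config: VisionConfig = field(default_factory=VisionConfig)

    def __call__(self, g: Genome, arena: Arena, seed: int) -> float:
        from .simulate import SimConfig, render_frames, simulate_experiment

        cfg = self.sim_config or SimConfig()
        result = simulate_experiment(g, arena, cfg, seed)
        return float(fitness_from_video(render_frames(result), self.vision_config))


def evaluate(
    g: Genome,
    arena: Arena,
    seed: int,
    sim_config=None,
    vision_config: VisionConfig | None = None,
) -> float:
    """Simulate one experiment, render its video and return the vision fitness."""
    return VisionEvaluator(sim_config, vision_config or VisionConfig())(g, arena, seed)


def ground_truth_evaluator(sim_config=None):
    """Evaluator that skips rendering and reads the simulator's own activity count.

    Useful for large campaigns: same experiments, fitness taken directly from
    the ground-truth trailing-3 s moving count the vision pipeline estimates.
    """
    from .simulate import SimConfig, simulate_experiment

    cfg = sim_config or SimConfig()

    def _eval(g: Genome, arena: Arena, seed: int) -> float:
        return float(simulate_experiment(g, arena, cfg, seed).final_active_count)

    return _eval
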