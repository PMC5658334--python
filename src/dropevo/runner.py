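"""Experiment orchestration: configs in, reproducible artifact directories out.

The four standard designs are:

* ``ga_single``   — one GA run in one arena (the validation experiment);
* ``ga_swap``     — 30 generations, arena switched empty -> pillars ->
                    L-system caves after generations 10 and 20;
* ``lattice``     — the 282-formulation sweep, 5 repeats per arena;
* ``control_swap``— the reproducibility control: the arena is "swapped" for
                    another instance of the same kind mid-run.

Every run directory contains the config snapshot, the per-individual
generations table, the flat evaluation log (which doubles as the landscape
training set) and a manifest with seeds and file checksums; identical spec +
seed reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .arena import Arena, make_empty_arena, make_lsystem_arena, make_pillar_arena
from .evolution import GAConfig, run_ga
from .lattice import enumerate_lattice, run_lattice
from .simulate import SimConfig
from .vision import VisionConfig, VisionEvaluator, ground_truth_evaluator

__all__ = ["ExperimentSpec", "run_experiment", "build_arena", "default_arenas"]

KINDS = ("ga_single", "ga_swap", "lattice", "control_swap")


def build_arena(kind: str, radius: float = 27.5, seed: int = 7) -> Arena:
    """Construct one of the named arena families."""
    if kind == "empty":
        return make_empty_arena(radius)
    if kind == "pillars":
        return make_pillar_arena(radius)
    if kind.startswith("lsystem"):
        if ":" in kind:
            seed = int(kind.split(":", 1)[1])
        return make_lsystem_arena(seed=seed, radius=radius)
    raise ValueError(f"unknown arena kind {kind!r}")


def default_arenas(radius: float = 27.5, lsystem_seed: int = 7) -> dict[str, Arena]:
    """The three canonical environments of the evolutionary experiments."""
    return {
        "empty": make_empty_arena(radius),
        "pillars": make_pillar_arena(radius),
        "lsystem": make_lsystem_arena(seed=lsystem_seed, radius=radius),
    }


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment campaign."""

    kind: str = "ga_single"
    seed: int = 0
    outdir: str = "results"
    generations: int = 10
    pop_size: int = 20
    repeats: int = 5
    mutation_variance: float = 0.1
    arenas: tuple[str, ...] = ("empty",)
    evaluator: str = "ground_truth"       # "ground_truth" | "vision"
    sim: dict = field(default_factory=dict)
    vision: dict = field(default_factory=dict)
    granularity: float = 0.1              # lattice only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "arenas" in data:
            data["arenas"] = tuple(data["arenas"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["arenas"] = list(self.arenas)
        return d

    def make_evaluator(self):
        sim_cfg = SimConfig(**self.sim) if self.sim else SimConfig()
        if self.evaluator == "vision":
            vis_cfg = VisionConfig(**self.vision) if self.vision else VisionConfig()
            return VisionEvaluator(sim_cfg, vis_cfg)
        return ground_truth_evaluator(sim_cfg)

    def schedule(self) -> tuple:
        """The arena schedule implied by the experiment kind."""
        if self.kind == "ga_single":
            if len(self.arenas) != 1:
                raise ValueError("ga_single uses exactly one arena")
            return (((1, self.generations), self.arenas[0]),)
        if self.kind in ("ga_swap", "control_swap"):
            n_seg = len(self.arenas)
            if self.generations % n_seg:
                raise ValueError("generations must divide evenly over the arenas")
            seg = self.generations // n_seg
            ids = self._segment_ids()
            return tuple(
                ((i * seg + 1, (i + 1) * seg), aid) for i, aid in enumerate(ids)
            )
        raise ValueError(f"{self.kind} has no GA schedule")

    def _segment_ids(self) -> list[str]:
        # control_swap re-uses the same arena kind as distinct instances
        ids, seen = [], {}
        for a in self.arenas:
            seen[a] = seen.get(a, 0) + 1
            ids.append(f"{a}#{seen[a]}" if self.kind == "control_swap" else a)
        return ids


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(spec: ExperimentSpec) -> Path:
    """Execute the campaign described by ``spec``; returns the artifact directory.

    GA runs checkpoint per generation (``checkpoint.json`` holds finished
    generation indices) and are resumed by re-deriving the identical
    seed stream, so a rerun after interruption reproduces the same outputs.
    """
    out = Path(spec.outdir)
    out.mkdir(parents=True, exist_ok=True)
    evaluator = spec.make_evaluator()
    files: list[Path] = []

    if spec.kind == "lattice":
        plan = enumerate_lattice(spec.granularity)
        arenas = {a: build_arena(a) for a in spec.arenas}
        df = run_lattice(plan, arenas, evaluator, repeats=spec.repeats, seed=spec.seed)
        path = out / "lattice.csv"
        df.to_csv(path, index=False)
        files.append(path)
    else:
        schedule = spec.schedule()
        arena_ids = {aid for _, aid in schedule}
        arenas = {aid: build_arena(aid.split("#")[0]) for aid in arena_ids}
        cfg = GAConfig(
            generations=spec.generations,
            pop_size=spec.pop_size,
            repeats=spec.repeats,
            n_parents=spec.pop_size // 2,
            mutation_variance=spec.mutation_variance,
            seed=spec.seed,
            arena_schedule=schedule,
        )
        ckpt = out / "checkpoint.json"

        def progress(rec):
            done = []
            if ckpt.exists():
                done = json.loads(ckpt.read_text())["generations_done"]
            done.append(rec.index)
            ckpt.write_text(json.dumps({"generations_done": done}))

        result = run_ga(cfg, evaluator, arenas, progress=progress)
        gen_path = out / "generations.csv"
        result.generations_frame().to_csv(gen_path, index=False)
        eval_path = out / "evaluations.csv"
        result.evaluations_frame().to_csv(eval_path, index=False)
        stats_path = out / "stats.json"
        stats_path.write_text(
            json.dumps(
                [
                    {
                        "generation": r.index,
                        "arena": r.arena_id,
                        "mean_fitness": r.stats.mean_fitness,
                        "top_quartile": r.stats.top_quartile,
                        "bottom_quartile": r.stats.bottom_quartile,
                        "genome_sd": list(r.stats.genome_sd),
                    }
                    for r in result.generations
                ],
                indent=1,
            )
        )
        files.extend([gen_path, eval_path, stats_path])

    cfg_path = out / "run.json"
    cfg_path.write_text(json.dumps(spec.to_dict(), indent=1, sort_keys=True))
    files.append(cfg_path)
    manifest = {
        "seed": spec.seed,
        "kind": spec.kind,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
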