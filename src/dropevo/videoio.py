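"""Reading and writing videos as PNG frame directories.

Experiments are exchanged as directories of numbered grayscale PNGs
(frame_000000.png, ...), the plain-text-adjacent format every tool in the
chain can read; in-memory frame iterators are accepted everywhere frames are
consumed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np

__all__ = ["write_frames", "read_frames"]


def write_frames(frames: Iterable[np.ndarray], outdir: str | Path) -> int:
    """Write frames as numbered PNGs; returns the number written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:06d}.png", np.asarray(frame, dtype=np.uint8))
        n = i + 1
    return n


def read_frames(indir: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from a PNG frame directory in frame order."""
    indir = Path(indir)
    files = sorted(indir.glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {indir}")
    for f in files:
        frame = iio.imread(f)
        if frame.ndim == 3:
            frame = frame[..., 0]
        yield np.asarray(frame, dtype=np.uint8)
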