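"""Readers, writers, and configuration for the maze pipeline.

Counts CSV dialect (version 1, declared in a leading comment line):

    # optomaze-counts-v1
    maze_id,strain,direction,n_loaded,count_m4,...,count_p4

``direction`` is +1 or −1; the nine count columns are tubes −4..+4 named
``count_m4 .. count_m1, count_0, count_p1 .. count_p4`` so the sign never
depends on CSV parsing of a leading minus.

Frame sequences are exported as numbered 8-bit RGB PNGs plus a JSON
sidecar carrying the full stimulus spec, geometry, and seed.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .maze_sim import (DEFAULT_FLIES_PER_MAZE, DEFAULT_LOSS_PROB, StrainParams,
                       TubeCounts)
from .stimuli import (DEFAULT_GEOMETRY, FrameSequence, ScreenGeometry,
                      spec_from_dict, spec_to_dict)

__all__ = [
    "COUNTS_HEADER",
    "COUNT_COLUMNS",
    "CountsFormatError",
    "read_counts_csv",
    "write_counts_csv",
    "write_frames",
    "read_frames",
    "ExperimentConfig",
]

COUNTS_HEADER = "# optomaze-counts-v1"
_TUBE_COLS = ["count_m4", "count_m3", "count_m2", "count_m1", "count_0",
              "count_p1", "count_p2", "count_p3", "count_p4"]
COUNT_COLUMNS = ["maze_id", "strain", "direction", "n_loaded"] + _TUBE_COLS


class CountsFormatError(ValueError):
    """A counts CSV violates the documented dialect."""


def write_counts_csv(records: Sequence[TubeCounts], path: Union[str, Path]) -> None:
    """Write maze records in the versioned counts dialect."""
    rows = []
    for r in records:
        row = {"maze_id": r.maze_id, "strain": r.strain,
               "direction": r.stimulus_direction, "n_loaded": r.n_loaded}
        row.update({col: int(c) for col, c in zip(_TUBE_COLS, r.counts)})
        rows.append(row)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(COUNTS_HEADER + "\n")
        df.to_csv(fh, index=False)


def read_counts_csv(path: Union[str, Path]) -> List[TubeCounts]:
    """Read and validate a counts CSV; malformed rows are reported by line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing columns {missing}")
    records = []
    # +3: 1-based, plus the version comment and the header line.
    for idx, row in df.iterrows():
        line = int(idx) + 3
        direction = row["direction"]
        if direction not in (1, -1):
            raise CountsFormatError(f"{path} line {line}: direction must be +1 or -1, "
                                    f"got {direction!r}")
        counts = row[_TUBE_COLS].to_numpy()
        try:
            counts = counts.astype(int)
        except (TypeError, ValueError) as exc:
            raise CountsFormatError(f"{path} line {line}: non-integer count") from exc
        if (counts < 0).any():
            raise CountsFormatError(f"{path} line {line}: negative tube count")
        try:
            records.append(TubeCounts(
                counts=counts, stimulus_direction=int(direction),
                strain=str(row["strain"]), maze_id=str(row["maze_id"]),
                n_loaded=int(row["n_loaded"]),
            ))
        except ValueError as exc:
            raise CountsFormatError(f"{path} line {line}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Frame sequence export
# ---------------------------------------------------------------------------

def write_frames(seq: FrameSequence, outdir: Union[str, Path],
                 spec=None) -> Path:
    """Export a movie as numbered PNGs plus a JSON sidecar; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq):
        Image.fromarray(frame, mode="RGB").save(outdir / f"frame_{i:05d}.png")
    sidecar = {
        "geometry": asdict(seq.geometry),
        "seed": seq.seed,
        "n_frames": len(seq),
        "spec": spec_to_dict(spec) if spec is not None else None,
    }
    with open(outdir / "stimulus.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return outdir


def read_frames(indir: Union[str, Path]) -> FrameSequence:
    """Load a PNG frame sequence written by :func:`write_frames`."""
    indir = Path(indir)
    paths = sorted(indir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {indir}")
    frames = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in paths])
    sidecar = indir / "stimulus.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        geometry = ScreenGeometry(**meta["geometry"])
        seed = meta.get("seed")
    else:
        geometry = ScreenGeometry(width_px=frames.shape[2], height_px=frames.shape[1])
        seed = None
    return FrameSequence(frames=frames, geometry=geometry, seed=seed)


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed for one end-to-end pipeline run."""

    stimulus: object
    geometry: ScreenGeometry = DEFAULT_GEOMETRY
    strains: Sequence[StrainParams] = ()
    n_mazes: int = 8
    n_flies_per_maze: int = DEFAULT_FLIES_PER_MAZE
    loss_prob: float = DEFAULT_LOSS_PROB
    n_frames: int = 60
    alpha_levels: Dict[str, float] = field(default_factory=lambda: {
        "vs_zero": 0.01, "strain": 0.01, "anova": 0.01, "correlation": 0.05,
    })
    master_seed: int = 0
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_mazes < 2 or self.n_flies_per_maze < 1:
            raise ValueError("n_mazes and n_flies_per_maze must be positive")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")
        if any(not (0 < a < 1) for a in self.alpha_levels.values()):
            raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        geometry = ScreenGeometry(**d.pop("geometry", {}))
        stimulus = spec_from_dict(d.pop("stimulus"))
        strains = tuple(StrainParams(**s) for s in d.pop("strains", []))
        out = d.pop("output_dir", None)
        return cls(stimulus=stimulus, geometry=geometry, strains=strains,
                   output_dir=Path(out) if out else None, **d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExperimentConfig":
        """Load a config from JSON or TOML, chosen by file extension."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        return cls.from_dict(json.loads(path.read_text()))
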