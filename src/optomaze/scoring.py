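"""Visual Response scoring of tube-count records.

The Visual Response (VR) of one maze is the weighted mean tube index of
the counted flies, ``VR = Σ_N N·count_N / Σ_N count_N`` for N = −4..+4,
sign-corrected by the stimulus direction so that following the stimulus
is positive. The maze — not the fly — is the statistical unit: strain
means and s.e.m. are computed across per-maze VRs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .maze_sim import TUBES, TubeCounts

__all__ = ["VRResult", "visual_response", "pooled_vr", "tube_proportions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VRResult:
    """Pooled Visual Response of a set of mazes (mean ± s.e.m. across mazes)."""

    vr_mean: float
    vr_sem: float
    per_maze_vr: List[float]
    n_mazes: int
    n_flies: int
    strain: str = ""

    def __post_init__(self) -> None:
        if abs(self.vr_mean) > 4 + 1e-12:
            raise ValueError("|VR| cannot exceed 4")
        if self.vr_sem < 0:
            raise ValueError("s.e.m. must be non-negative")


def visual_response(record: TubeCounts) -> float:
    """Direction-corrected VR of one maze; errors on a zero-count maze."""
    total = record.n_counted
    if total == 0:
        raise ValueError(f"maze {record.maze_id!r} has no counted flies")
    weighted = float(np.dot(TUBES, record.counts)) / total
    return record.stimulus_direction * weighted


def pooled_vr(records: Sequence[TubeCounts], strain: str = "") -> VRResult:
    """Per-maze VRs pooled across a direction-balanced experiment.

    Mazes with zero counted flies are excluded (and logged), never scored
    as 0 — scoring them 0 would bias the pooled mean toward the null.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("pooling requires at least 2 maze records")
    vrs, n_flies = [], 0
    for r in records:
        if r.n_counted == 0:
            logger.warning("excluding maze %r: zero counted flies", r.maze_id)
            continue
        vrs.append(visual_response(r))
        n_flies += r.n_counted
    if not vrs:
        raise ValueError("all maze records are empty")
    arr = np.asarray(vrs)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    if not strain:
        labels = {r.strain for r in records if r.strain}
        strain = labels.pop() if len(labels) == 1 else ""
    return VRResult(vr_mean=float(arr.mean()), vr_sem=sem, per_maze_vr=vrs,
                    n_mazes=arr.size, n_flies=n_flies, strain=strain)


def tube_proportions(records: Sequence[TubeCounts]) -> Tuple[np.ndarray, np.ndarray]:
    """Mean ± s.e.m. per-tube proportion across mazes, direction-corrected.

    For mazes run with the stimulus moving leftward the count vector is
    reversed before pooling, so tube +4 always means "followed the
    stimulus through every junction". Proportions within each maze sum
    to 1. Returns ``(mean, sem)`` arrays over tubes −4..+4.
    """
    props = []
    for r in records:
        if r.n_counted == 0:
            logger.warning("excluding maze %r: zero counted flies", r.maze_id)
            continue
        c = r.counts if r.stimulus_direction == 1 else r.counts[::-1]
        props.append(c / r.n_counted)
    if not props:
        raise ValueError("no records with counted flies")
    mat = np.asarray(props)
    mean = mat.mean(axis=0)
    sem = (mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
           if mat.shape[0] > 1 else np.zeros(9))
    return mean, sem
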