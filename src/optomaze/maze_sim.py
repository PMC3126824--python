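"""Agent-based simulator of the 8-junction binary-choice maze.

Populations of flies walk through a maze of 8 sequential T-junctions with
9 ranked exit tubes (−4..+4). Each counted fly makes 8 independent
Bernoulli choices toward or away from the stimulus direction; its exit
tube is half the signed excess of toward-choices, so the tube distribution
of counted flies is Binomial(8, p) shifted to −4..+4 and the expected
Visual Response is 4(2p − 1). Flies can be lost in the maze (excluded
from the tally) independently of their choice behavior.

This is the null behavioral model of the assay: junction choices are
i.i.d. within and across flies, with no momentum or alternation, matching
the population-level readout of the hardware (per-tube infrared counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "StrainParams",
    "TubeCounts",
    "TUBES",
    "WILD_TYPE",
    "DUNCE1",
    "tube_from_choices",
    "simulate_maze",
    "psychometric_bias",
    "simulate_experiment",
    "estimate_p",
]

TUBES = np.arange(-4, 5)  # tube indices N

DEFAULT_FLIES_PER_MAZE = 25   # "batches of ~25" loaded per maze
DEFAULT_LOSS_PROB = 0.05      # fraction stuck in the maze and excluded


@dataclass(frozen=True)
class StrainParams:
    """Behavioral phenotype of a strain as a saturating psychometric curve.

    ``p_max`` is the per-junction turn probability toward the stimulus at
    saturating salience; ``salience_gain`` sets how fast the bias grows
    with stimulus salience; ``baseline_asymmetry`` is a stimulus-independent
    left/right bias (positive = rightward), cancelled in expectation by
    direction-balanced experiments.
    """

    name: str
    p_max: float = 0.62
    salience_gain: float = 8.0
    baseline_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if not (0.5 < self.p_max <= 1.0):
            raise ValueError("p_max must lie in (0.5, 1]")
        if self.salience_gain < 0:
            raise ValueError("salience_gain must be >= 0")


# Phenotype presets. The mutant's stronger response to high-contrast,
# highly structured motion is encoded as a higher saturation level and a
# steeper salience gain than wild type.
WILD_TYPE = StrainParams(name="wild_type", p_max=0.60, salience_gain=8.0)
DUNCE1 = StrainParams(name="dunce1", p_max=0.70, salience_gain=12.0)


@dataclass(frozen=True)
class TubeCounts:
    """One maze run: per-tube counts in absolute coordinates.

    ``counts[i]`` is the number of flies in tube ``TUBES[i]`` (−4..+4).
    ``n_loaded`` minus the counted total is the number of flies lost in
    the maze and excluded from the tally.
    """

    counts: np.ndarray
    stimulus_direction: int
    strain: str = ""
    maze_id: str = ""
    n_loaded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (9,):
            raise ValueError("counts must hold exactly 9 tubes (−4..+4)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.stimulus_direction not in (1, -1):
            raise ValueError("stimulus_direction must be +1 or -1")
        n_loaded = self.n_loaded if self.n_loaded else int(c.sum())
        if int(c.sum()) > n_loaded:
            raise ValueError("counted flies exceed n_loaded")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "n_loaded", int(n_loaded))

    @property
    def n_counted(self) -> int:
        return int(self.counts.sum())


def tube_from_choices(choices: Sequence[int]) -> int:
    """Exit tube of a fly from its 8 junction choices (±1 each).

    The binary tree forces the exit to ``(#right − #left) / 2``, an
    integer in [−4, +4].
    """
    choices = list(choices)
    if len(choices) != 8:
        raise ValueError(f"a fly makes exactly 8 choices, got {len(choices)}")
    if any(c not in (1, -1) for c in choices):
        raise ValueError("choices must be +1 or -1")
    return sum(choices) // 2


def simulate_maze(n_flies: int, p_turn: float, loss_prob: float = DEFAULT_LOSS_PROB,
                  stimulus_direction: int = 1, seed: int = 0, strain: str = "",
                  maze_id: str = "") -> TubeCounts:
    """Simulate one maze run of ``n_flies`` independent flies.

    Each fly is lost with probability ``loss_prob`` (excluded from the
    counts but included in ``n_loaded``); otherwise it makes 8 independent
    Bernoulli(``p_turn``) choices toward the stimulus direction. Counts
    are reported in absolute tube coordinates: with ``stimulus_direction
    == -1`` the tube sign is mirrored.
    """
    if n_flies <= 0:
        raise ValueError("n_flies must be positive")
    if not (0.0 <= p_turn <= 1.0):
        raise ValueError("p_turn must lie in [0, 1]")
    if not (0.0 <= loss_prob < 1.0):
        raise ValueError("loss_prob must lie in [0, 1)")
    if stimulus_direction not in (1, -1):
        raise ValueError("stimulus_direction must be +1 or -1")
    rng = np.random.default_rng(seed)
    counted = n_flies - int(rng.binomial(n_flies, loss_prob))
    counts = np.zeros(9, dtype=int)
    if counted:
        toward = rng.binomial(8, p_turn, size=counted)        # choices toward stimulus
        tubes = stimulus_direction * (toward - 4)             # absolute tube index
        counts = np.bincount(tubes + 4, minlength=9)
    return TubeCounts(counts=counts, stimulus_direction=stimulus_direction,
                      strain=strain, maze_id=maze_id, n_loaded=n_flies)


def psychometric_bias(salience: float, strain: StrainParams) -> float:
    """Per-junction turn probability toward the stimulus at a given salience.

    ``p = 0.5 + (p_max − 0.5)·(1 − exp(−gain·salience)) + asymmetry``,
    clamped to [0, 1]. Zero salience gives 0.5 plus the baseline asymmetry.
    """
    if salience < 0:
        raise ValueError("salience must be >= 0")
    p = 0.5 + (strain.p_max - 0.5) * (1.0 - math.exp(-strain.salience_gain * salience))
    return float(min(1.0, max(0.0, p + strain.baseline_asymmetry)))


def _p_toward(salience: float, strain: StrainParams, direction: int) -> float:
    """Turn probability toward the stimulus for a given absolute direction.

    The baseline asymmetry is a fixed left/right bias, so it aids the
    stimulus when motion is rightward (+1) and opposes it when leftward.
    """
    p = 0.5 + (strain.p_max - 0.5) * (1.0 - math.exp(-strain.salience_gain * salience))
    return float(min(1.0, max(0.0, p + direction * strain.baseline_asymmetry)))


def simulate_experiment(strain: StrainParams, salience: float, n_mazes: int = 8,
                        n_flies_per_maze: int = DEFAULT_FLIES_PER_MAZE,
                        loss_prob: float = DEFAULT_LOSS_PROB,
                        seed: int = 0) -> List[TubeCounts]:
    """Simulate a direction-balanced experiment.

    Half the mazes run with the stimulus moving rightward (+1) and half
    leftward (−1), mirroring hardware runs balanced for image direction.
    Per-maze seeds are drawn once from the master seed, so the whole
    experiment is reproducible and individual mazes can be re-run.
    """
    if n_mazes < 2 or n_mazes % 2 != 0:
        raise ValueError("n_mazes must be an even number >= 2 (half per direction)")
    if salience < 0:
        raise ValueError("salience must be >= 0")
    rng = np.random.default_rng(seed)
    maze_seeds = rng.integers(0, 2 ** 31 - 1, size=n_mazes)
    records = []
    for i in range(n_mazes):
        direction = 1 if i < n_mazes // 2 else -1
        p = _p_toward(salience, strain, direction)
        records.append(simulate_maze(
            n_flies=n_flies_per_maze, p_turn=p, loss_prob=loss_prob,
            stimulus_direction=direction, seed=int(maze_seeds[i]),
            strain=strain.name, maze_id=f"{strain.name}_m{i:03d}",
        ))
    return records


def estimate_p(records: Sequence[TubeCounts]) -> Tuple[float, Tuple[float, float]]:
    """Invert the binomial maze model: per-junction turn probability.

    Each counted fly in (direction-corrected) tube N made ``N + 4`` of its
    8 choices toward the stimulus, so the pooled toward-choice count is
    binomial over ``8 × (total flies)`` trials. Returns the point estimate
    and a normal-approximation 95% CI on that binomial.
    """
    records = list(records)
    total = sum(r.n_counted for r in records)
    if not records or total == 0:
        raise ValueError("no counted flies in any record")
    successes = 0
    for r in records:
        tubes_stim = r.stimulus_direction * TUBES  # tube index in stimulus frame
        successes += int(np.dot(r.counts, tubes_stim + 4))
    trials = 8 * total
    p_hat = successes / trials
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / trials)
    ci = (max(0.0, p_hat - 1.959963984540054 * se),
          min(1.0, p_hat + 1.959963984540054 * se))
    return p_hat, ci
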