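"""Trial-structure generation for the chimeric face/scene betting task.

The task has two phases: a solo classification phase (C1) and a repeat
phase (C2) in which a partner bets on the upcoming image category before
the participant responds. Stimulus ambiguity is summarised by a single
scalar, the percentage of "scene" in the image (0-100). Bets are assigned
so that an exact, design-enforced fraction of them is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SCENE = "scene"
FACE = "face"
COOPERATION = "cooperation"
COMPETITION = "competition"
CONDITIONS = (COOPERATION, COMPETITION)

#: Default ambiguity grid: 11 equally spaced levels spanning the full range.
DEFAULT_SCENE_GRID: Tuple[int, ...] = tuple(range(0, 101, 10))

#: Payoff in signed cents keyed by (condition, participant_correct, bet_correct).
#: Cells with an incorrect bet carry no transfer.
DEFAULT_PAYOFF_TABLE: Mapping[Tuple[str, int, int], int] = {
    (COOPERATION, 1, 1): 10,
    (COOPERATION, 0, 1): 0,
    (COOPERATION, 1, 0): 0,
    (COOPERATION, 0, 0): 0,
    (COMPETITION, 1, 1): -4,
    (COMPETITION, 0, 1): -7,
    (COMPETITION, 1, 0): 0,
    (COMPETITION, 0, 0): 0,
}


class TaskConfigError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one experiment run.

    Parameters
    ----------
    n_trials
        Number of trials per phase.
    scene_grid
        Ambiguity levels (percent scene) tiled to fill ``n_trials``.
    condition
        ``"cooperation"`` or ``"competition"``.
    bet_accuracy
        Fraction of C2 bets that match the true category. The two
        published designs use 0.5 and 0.75; any value in [0, 1] is valid.
    payoff_table
        Mapping (condition, participant_correct, bet_correct) -> signed cents.
    seed
        Seed for all sequence randomisation.
    """

    n_trials: int = 80
    scene_grid: Tuple[float, ...] = DEFAULT_SCENE_GRID
    condition: str = COOPERATION
    bet_accuracy: float = 0.5
    payoff_table: Mapping[Tuple[str, int, int], int] = field(
        default_factory=lambda: dict(DEFAULT_PAYOFF_TABLE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise TaskConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if len(self.scene_grid) == 0:
            raise TaskConfigError("scene_grid must not be empty")
        grid = np.asarray(self.scene_grid, dtype=float)
        if np.any(grid < 0) or np.any(grid > 100):
            raise TaskConfigError("scene_grid values must lie in [0, 100]")
        if self.condition not in CONDITIONS:
            raise TaskConfigError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.bet_accuracy <= 1.0:
            raise TaskConfigError(
                f"bet_accuracy must lie in [0, 1], got {self.bet_accuracy}"
            )


def experiment_config(
    experiment: int, condition: str = COOPERATION, seed: int = 0, **overrides
) -> TaskConfig:
    """Return the published design for experiment 1 (50% accurate bets) or 2 (75%)."""
    if experiment not in (1, 2):
        raise TaskConfigError(f"experiment must be 1 or 2, got {experiment}")
    accuracy = 0.5 if experiment == 1 else 0.75
    return TaskConfig(condition=condition, bet_accuracy=accuracy, seed=seed, **overrides)


@dataclass(frozen=True)
class TrialSequence:
    """One phase's trial-by-trial structure.

    Arrays are aligned; ``bet_direction``/``bet_correct`` may be absent
    (C1 phase has no bets). Categories are encoded as 1 = scene, 0 = face.
    """

    scene_pct: np.ndarray
    true_category: np.ndarray
    ambiguous_truth: np.ndarray
    bet_direction: Optional[np.ndarray] = None
    bet_correct: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.scene_pct)
        for name in ("true_category", "ambiguous_truth", "bet_direction", "bet_correct"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.bet_direction is not None and self.bet_correct is not None:
            expect = (self.bet_direction == self.true_category).astype(int)
            if not np.array_equal(expect, self.bet_correct):
                raise ValueError("bet_correct inconsistent with bet_direction")

    @property
    def n_trials(self) -> int:
        return len(self.scene_pct)

    @property
    def has_bets(self) -> bool:
        return self.bet_direction is not None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_idx": np.arange(self.n_trials),
                "scene_pct": self.scene_pct,
                "true_category": np.where(self.true_category == 1, SCENE, FACE),
            }
        )
        if self.has_bets:
            df["bet_direction"] = np.where(self.bet_direction == 1, SCENE, FACE)
            df["bet_correct"] = self.bet_correct
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSequence":
        scene_pct = df["scene_pct"].to_numpy(dtype=float)
        true_cat = (df["true_category"].to_numpy() == SCENE).astype(int)
        bet_dir = bet_corr = None
        if "bet_direction" in df.columns and df["bet_direction"].notna().all():
            bet_dir = (df["bet_direction"].to_numpy() == SCENE).astype(int)
            bet_corr = (bet_dir == true_cat).astype(int)
        return cls(
            scene_pct=scene_pct,
            true_category=true_cat,
            ambiguous_truth=(scene_pct == 50.0),
            bet_direction=bet_dir,
            bet_correct=bet_corr,
        )


def generate_stimulus_sequence(config: TaskConfig) -> TrialSequence:
    """Generate the shuffled stimulus sequence for one phase.

    The scene grid is tiled to at least ``n_trials`` entries, a seeded
    permutation selects and orders the trials, and the true category is
    scene above 50%, face below, and a seeded coin flip at exactly 50%
    (such trials are flagged ``ambiguous_truth``).
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.scene_grid, dtype=float)
    reps = int(np.ceil(config.n_trials / len(grid)))
    tiled = np.tile(grid, reps)
    scene_pct = rng.permutation(tiled)[: config.n_trials]
    ambiguous = scene_pct == 50.0
    true_category = (scene_pct > 50.0).astype(int)
    true_category[ambiguous] = rng.integers(0, 2, size=int(ambiguous.sum()))
    return TrialSequence(
        scene_pct=scene_pct, true_category=true_category, ambiguous_truth=ambiguous
    )


def generate_bets(
    trials: TrialSequence, bet_accuracy: float, seed: int = 0
) -> TrialSequence:
    """Assign bet directions so that exactly round(accuracy * n) bets are correct.

    Which trials receive a correct bet is a seeded uniform draw without
    replacement; the count itself is design-enforced, not sampled.
    """
    if not 0.0 <= bet_accuracy <= 1.0:
        raise ValueError(f"bet_accuracy must lie in [0, 1], got {bet_accuracy}")
    rng = np.random.default_rng(seed)
    n = trials.n_trials
    n_correct = int(round(bet_accuracy * n))
    correct_idx = rng.choice(n, size=n_correct, replace=False)
    bet_correct = np.zeros(n, dtype=int)
    bet_correct[correct_idx] = 1
    bet_direction = np.where(bet_correct == 1, trials.true_category, 1 - trials.true_category)
    return replace(trials, bet_direction=bet_direction, bet_correct=bet_correct)


def generate_task(config: TaskConfig) -> Tuple[TrialSequence, TrialSequence]:
    """Build the (C1, C2) pair: same stimuli in both phases, bets only in C2."""
    c1 = generate_stimulus_sequence(config)
    c2 = generate_bets(c1, config.bet_accuracy, seed=config.seed + 1)
    return c1, c2


def payoff(
    condition: str,
    participant_correct: int,
    bet_correct: int,
    table: Optional[Mapping[Tuple[str, int, int], int]] = None,
) -> int:
    """Signed payoff in cents for one C2 trial outcome."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if participant_correct not in (0, 1) or bet_correct not in (0, 1):
        raise ValueError("participant_correct and bet_correct must be 0 or 1")
    lookup = DEFAULT_PAYOFF_TABLE if table is None else table
    return lookup[(condition, int(participant_correct), int(bet_correct))]
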