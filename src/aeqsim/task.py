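"""Acquired-equivalence task environment.

The task presents an antecedent stimulus (one of four faces) together with
two consequent options (two of four coloured fish), one on each side of the
screen; the subject picks a side and, on feedback trials, is told whether
the chosen fish is the one trained for that face.

Stages
------
``shaping``              A1→X1, B1→Y1 (feedback)
``equivalence_training`` A2→X1, B2→Y1 (feedback) — A2/B2 acquire equivalence
                         with A1/B1 through the shared consequents
``new_consequent``       A1→X2, B1→Y2 (feedback)
``transfer``             A2→X2, B2→Y2 — never-trained pairings implied by the
                         acquired equivalence; feedback withheld by default

The first three stages form the acquisition phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "ANTECEDENTS",
    "CONSEQUENTS",
    "STAGES",
    "ACQUISITION_STAGES",
    "StimulusSet",
    "TrialSpec",
    "InputVector",
    "bit_index",
    "build_task",
    "build_task_from_counts",
    "encode_trial",
    "give_feedback",
    "trials_to_frame",
]

ANTECEDENTS = ("A1", "A2", "B1", "B2")
CONSEQUENTS = ("X1", "X2", "Y1", "Y2")

STAGES = ("shaping", "equivalence_training", "new_consequent", "transfer")
ACQUISITION_STAGES = STAGES[:3]

# (antecedent, correct consequent, foil consequent) per stage.  The foil is
# always the other family's consequent of the same novelty, matching the
# two-fish screen layout of the task.
_STAGE_PAIRS: dict[str, tuple[tuple[str, str, str], ...]] = {
    "shaping": (("A1", "X1", "Y1"), ("B1", "Y1", "X1")),
    "equivalence_training": (("A2", "X1", "Y1"), ("B2", "Y1", "X1")),
    "new_consequent": (("A1", "X2", "Y2"), ("B1", "Y2", "X2")),
    "transfer": (("A2", "X2", "Y2"), ("B2", "Y2", "X2")),
}

TRAINED_PAIRS = frozenset(
    (a, c) for s in ACQUISITION_STAGES for a, c, _ in _STAGE_PAIRS[s]
)
NOVEL_PAIRS = frozenset((a, c) for a, c, _ in _STAGE_PAIRS["transfer"])


class ConfigurationError(ValueError):
    """Raised for invalid task/sweep configuration values."""


@dataclass(frozen=True)
class StimulusSet:
    """The four faces, four fish and the stage→pair map of the task."""

    antecedents: tuple[str, ...] = ANTECEDENTS
    consequents: tuple[str, ...] = CONSEQUENTS
    trained_pairs: Mapping[str, tuple[tuple[str, str, str], ...]] = field(
        default_factory=lambda: dict(_STAGE_PAIRS)
    )

    def __post_init__(self) -> None:
        if len(self.antecedents) != 4 or len(self.consequents) != 4:
            raise ConfigurationError("need exactly 4 antecedents and 4 consequents")
        trained = {
            (a, c)
            for s in ACQUISITION_STAGES
            for a, c, _ in self.trained_pairs[s]
        }
        novel = {(a, c) for a, c, _ in self.trained_pairs["transfer"]}
        if trained != set(TRAINED_PAIRS) or novel != set(NOVEL_PAIRS):
            raise ConfigurationError("stage→pair map violates the task structure")


@dataclass(frozen=True)
class TrialSpec:
    """One two-alternative forced-choice trial."""

    stage: str
    antecedent: str
    left_option: str
    right_option: str
    correct_side: str  # "left" | "right", pointing at the trained consequent
    feedback: bool

    def __post_init__(self) -> None:
        if self.left_option == self.right_option:
            raise ConfigurationError("the two options must differ")
        if self.correct_side not in ("left", "right"):
            raise ConfigurationError("correct_side must be 'left' or 'right'")

    @property
    def correct_option(self) -> str:
        return self.left_option if self.correct_side == "left" else self.right_option


@dataclass(frozen=True)
class InputVector:
    """Binary model input: 16 task bits plus a 4-unit thermometer code.

    ``task_bits[i]`` flags the (antecedent, consequent) combination with
    ``i = 4 * antecedent_index + consequent_index`` (row-major over the
    orderings in :data:`ANTECEDENTS` / :data:`CONSEQUENTS`); exactly the two
    on-screen combinations are set.  The number of active hippocampus units
    equals the integer strength 0–4.
    """

    task_bits: np.ndarray
    hippocampus_units: np.ndarray
    strength: int


def bit_index(antecedent: str, consequent: str) -> int:
    """Row-major index of an (antecedent, consequent) combination in 0..15."""
    return ANTECEDENTS.index(antecedent) * 4 + CONSEQUENTS.index(consequent)


def encode_trial(trial: TrialSpec, strength: int) -> InputVector:
    """Encode a trial as the model's 20-component binary input."""
    if strength not in (0, 1, 2, 3, 4):
        raise ValueError(f"hippocampus strength must be in 0..4, got {strength!r}")
    bits = np.zeros(16, dtype=np.int8)
    bits[bit_index(trial.antecedent, trial.left_option)] = 1
    bits[bit_index(trial.antecedent, trial.right_option)] = 1
    units = np.zeros(4, dtype=np.int8)
    units[:strength] = 1
    return InputVector(task_bits=bits, hippocampus_units=units, strength=strength)


def give_feedback(trial: TrialSpec, action: str) -> float | None:
    """Reward for an action: 1.0 correct / 0.0 incorrect, ``None`` when the
    trial carries no feedback (probe trials; the learner must not update)."""
    if not trial.feedback:
        return None
    return 1.0 if action == trial.correct_side else 0.0


def _stage_trials(
    stage: str,
    pairs: Sequence[tuple[str, str, str, bool]],
    n_trials: int,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """Equal pair counts and ~50/50 side placement, then shuffled."""
    n_pairs = len(pairs)
    base, extra = divmod(n_trials, n_pairs)
    counts = [base] * n_pairs
    for i in rng.choice(n_pairs, size=extra, replace=False):
        counts[i] += 1
    trials: list[TrialSpec] = []
    for (ant, correct, foil, feedback), count in zip(pairs, counts):
        sides = ["left"] * (count // 2) + ["right"] * (count // 2)
        if count % 2:
            sides.append("left" if rng.random() < 0.5 else "right")
        for side in sides:
            left, right = (correct, foil) if side == "left" else (foil, correct)
            trials.append(
                TrialSpec(
                    stage=stage,
                    antecedent=ant,
                    left_option=left,
                    right_option=right,
                    correct_side=side,
                    feedback=feedback,
                )
            )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def build_task(
    blocks_per_stage: Mapping[str, int],
    trials_per_block: int = 8,
    seed: int = 0,
    *,
    transfer_feedback: bool = False,
    transfer_includes_trained: bool = False,
) -> list[TrialSpec]:
    """Build a full trial sequence, stage by stage.

    Within each block every active pair appears equally often (up to the
    divisibility remainder, assigned at random) and the correct option's
    side is counterbalanced.  Fully reproducible from ``seed``.
    """
    for stage in STAGES:
        n = blocks_per_stage.get(stage, 0)
        if n < 1:
            raise ConfigurationError(f"block count for stage {stage!r} must be >= 1")
    if trials_per_block < 1:
        raise ConfigurationError("trials_per_block must be >= 1")
    counts = {
        stage: blocks_per_stage[stage] * trials_per_block for stage in STAGES
    }
    return build_task_from_counts(
        counts,
        seed,
        transfer_feedback=transfer_feedback,
        transfer_includes_trained=transfer_includes_trained,
    )


def build_task_from_counts(
    trials_per_stage: Mapping[str, int],
    seed: int = 0,
    *,
    transfer_feedback: bool = False,
    transfer_includes_trained: bool = False,
) -> list[TrialSpec]:
    """Build a trial sequence from raw per-stage trial counts.

    Used when sessions are sized from subject block averages, which need not
    be multiples of the block length.
    """
    trials: list[TrialSpec] = []
    for stage in STAGES:
        n = int(trials_per_stage.get(stage, 0))
        if n < 1:
            raise ConfigurationError(f"trial count for stage {stage!r} must be >= 1")
        rng = substream(seed, "task", stage)
        if stage == "transfer":
            # Novel probes follow the configured feedback policy; retested
            # trained pairs, when included, keep their feedback.
            pairs = [(a, c, f, transfer_feedback) for a, c, f in _STAGE_PAIRS[stage]]
            if transfer_includes_trained:
                for s in ACQUISITION_STAGES:
                    pairs.extend((a, c, f, True) for a, c, f in _STAGE_PAIRS[s])
        else:
            pairs = [(a, c, f, True) for a, c, f in _STAGE_PAIRS[stage]]
        trials.extend(_stage_trials(stage, pairs, n, rng))
    return trials


def trials_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    """One row per trial: stage, antecedent, options, correct side, feedback."""
    trials = list(trials)
    return pd.DataFrame(
        {
            "trial": range(len(trials)),
            "stage": [t.stage for t in trials],
            "antecedent": [t.antecedent for t in trials],
            "left_option": [t.left_option for t in trials],
            "right_option": [t.right_option for t in trials],
            "correct_side": [t.correct_side for t in trials],
            "feedback": [t.feedback for t in trials],
        }
    )
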