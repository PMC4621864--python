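"""Synthetic subject cohorts.

The original behavioural study fed the simulator with each participant's
average number of task blocks per stage and summarised behaviour as mean
accuracy per phase; the raw per-subject numbers are not published.  This
module generates stand-in cohorts with the study's structure — two groups
(patient / control) of equal size, per-stage block averages, and per-phase
accuracies that are statistically indistinguishable between groups under
the defaults (the study's null result).  A configurable impairment knob
lowers the patient group's accuracy targets for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._seeding import substream
from .stats import rank_sum_test
from .task import STAGES

__all__ = [
    "GROUPS",
    "CohortParams",
    "SubjectProfile",
    "generate_cohort",
    "trials_from_profile",
    "cohort_to_frame",
    "cohort_from_frame",
    "compare_groups",
]

GROUPS = ("patient", "control")

#: Default mean blocks per stage (8 trials per block): 4 blocks for each
#: acquisition stage and 2 for transfer give 112-trial sessions.
DEFAULT_BLOCK_MEANS: dict[str, float] = {
    "shaping": 4.0,
    "equivalence_training": 4.0,
    "new_consequent": 4.0,
    "transfer": 2.0,
}


@dataclass(frozen=True)
class CohortParams:
    """Group-level generative parameters for synthetic subjects.

    Accuracies are truncated-normal in [0.5, 1] (above chance after
    training); block counts are truncated-normal with a floor of 1 block.
    ``impairment`` is subtracted from the patient group's accuracy means,
    zero by default (no group difference).
    """

    block_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_MEANS)
    )
    block_sd: float = 0.5
    accuracy_acquisition: float = 0.82
    accuracy_transfer: float = 0.78
    accuracy_sd: float = 0.06
    impairment: float = 0.0

    def __post_init__(self) -> None:
        if self.block_sd < 0 or self.accuracy_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.impairment <= 0.5:
            raise ValueError("impairment must be in [0, 0.5]")
        for stage in STAGES:
            if self.block_means.get(stage, 0) <= 0:
                raise ValueError(f"block mean for stage {stage!r} must be > 0")


@dataclass(frozen=True)
class SubjectProfile:
    """One synthetic subject: block averages and per-phase accuracy."""

    subject_id: str
    group: str
    blocks: Mapping[str, float]
    accuracy_acquisition: float
    accuracy_transfer: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        for stage, n in self.blocks.items():
            if n <= 0:
                raise ValueError(f"block count for {stage!r} must be positive")
        for acc in (self.accuracy_acquisition, self.accuracy_transfer):
            if not 0.5 <= acc <= 1.0:
                raise ValueError("accuracy must lie in [0.5, 1]")


def _trunc_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_per_group: int = 5,
    params: CohortParams | None = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw a balanced two-group cohort of synthetic subjects.

    Under default parameters the two groups come from identical
    distributions, so any accuracy difference is sampling noise.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = params or CohortParams()
    cohort: list[SubjectProfile] = []
    for group in GROUPS:
        rng = substream(seed, "cohort", group)
        decrement = params.impairment if group == "patient" else 0.0
        acq_mean = max(0.5, params.accuracy_acquisition - decrement)
        tra_mean = max(0.5, params.accuracy_transfer - decrement)
        acq = _trunc_normal(acq_mean, params.accuracy_sd, 0.5, 1.0, rng, n_per_group)
        tra = _trunc_normal(tra_mean, params.accuracy_sd, 0.5, 1.0, rng, n_per_group)
        blocks = {
            stage: _trunc_normal(
                params.block_means[stage], params.block_sd, 1.0, np.inf, rng,
                n_per_group,
            )
            for stage in STAGES
        }
        for i in range(n_per_group):
            cohort.append(
                SubjectProfile(
                    subject_id=f"{group[:3]}{i + 1:02d}",
                    group=group,
                    blocks={stage: float(blocks[stage][i]) for stage in STAGES},
                    accuracy_acquisition=float(acq[i]),
                    accuracy_transfer=float(tra[i]),
                    noise_sd=params.accuracy_sd,
                )
            )
    return cohort


def trials_from_profile(
    profile: SubjectProfile, trials_per_block: int = 8
) -> dict[str, int]:
    """Per-stage trial counts: block mean × block length, floored at 1."""
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    return {
        stage: max(1, round(profile.blocks[stage] * trials_per_block))
        for stage in STAGES
    }


def cohort_to_frame(cohort: Sequence[SubjectProfile]) -> pd.DataFrame:
    """One row per subject; block columns prefixed ``blocks_``."""
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "accuracy_acquisition": s.accuracy_acquisition,
            "accuracy_transfer": s.accuracy_transfer,
            "noise_sd": s.noise_sd,
        }
        row.update({f"blocks_{stage}": s.blocks[stage] for stage in STAGES})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(frame: pd.DataFrame) -> list[SubjectProfile]:
    """Inverse of :func:`cohort_to_frame`."""
    return [
        SubjectProfile(
            subject_id=str(r["subject_id"]),
            group=str(r["group"]),
            blocks={stage: float(r[f"blocks_{stage}"]) for stage in STAGES},
            accuracy_acquisition=float(r["accuracy_acquisition"]),
            accuracy_transfer=float(r["accuracy_transfer"]),
            noise_sd=float(r["noise_sd"]),
        )
        for _, r in frame.iterrows()
    ]


def compare_groups(cohort: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Exact rank-sum comparison of the groups' accuracies, per phase."""
    rows = []
    for phase, attr in (
        ("acquisition", "accuracy_acquisition"),
        ("transfer", "accuracy_transfer"),
    ):
        pat = [getattr(s, attr) for s in cohort if s.group == "patient"]
        con = [getattr(s, attr) for s in cohort if s.group == "control"]
        u, p = rank_sum_test(pat, con)
        rows.append(
            {
                "phase": phase,
                "patient_mean": float(np.mean(pat)),
                "control_mean": float(np.mean(con)),
                "U": u,
                "p_exact_two_sided": p,
            }
        )
    return pd.DataFrame(rows)
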