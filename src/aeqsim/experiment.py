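"""Parameter sweeps over hippocampus strength and basal-ganglia learning rate.

Two summary metrics are taken per simulated session:

* firing-rate % — the percentage of trials on which the winner-take-all
  output (the chosen action) matched the rewarded side;
* weight-update % — the percentage of updating trials on which the correct
  action's value increased, i.e. the basal-ganglia update moved in the
  task-appropriate direction.

Both anchor at ~50% for a chance-level agent, which is how the absent
hippocampus condition (strength 0, softmax slope 0) reads out.  Sessions
with learning disabled (learning rate 0) have no updating trials; their
weight-update % is reported as 50 with an explicit degenerate flag so
sweep grids that include the 0 column stay complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import substream
from .agent import Agent, AgentConfig, TrialOutcome, run_session
from .cohort import GROUPS, SubjectProfile, trials_from_profile
from .task import ACQUISITION_STAGES, ConfigurationError, build_task_from_counts

__all__ = [
    "SweepGrid",
    "SweepResult",
    "firing_rate_percent",
    "weight_update_percent",
    "accuracy_by_phase",
    "run_condition",
    "summarize_table",
]

DEFAULT_LEARNING_RATES = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def firing_rate_percent(trace: Sequence[TrialOutcome]) -> float:
    """Percentage of trials whose chosen action matched the correct side."""
    if len(trace) == 0:
        raise ValueError("firing_rate_percent needs a non-empty trace")
    return 100.0 * sum(o.correct for o in trace) / len(trace)


def weight_update_percent(trace: Sequence[TrialOutcome]) -> tuple[float, bool]:
    """Percentage of updating trials with a correct-direction value move.

    Returns ``(percentage, degenerate)``; a session without any updating
    trial (learning rate 0, or all-probe traces) is degenerate and reported
    at the 50% chance anchor.
    """
    if len(trace) == 0:
        raise ValueError("weight_update_percent needs a non-empty trace")
    updating = [o for o in trace if o.updating]
    if not updating:
        return 50.0, True
    hits = sum(bool(o.correct_value_increased) for o in updating)
    return 100.0 * hits / len(updating), False


def accuracy_by_phase(trace: Sequence[TrialOutcome]) -> tuple[float, float]:
    """(acquisition, transfer) accuracy of a session trace, both in [0, 1].

    Acquisition pools the shaping, equivalence-training and new-consequent
    stages; transfer covers transfer-stage trials only.
    """
    acq = [o.correct for o in trace if o.stage in ACQUISITION_STAGES]
    tra = [o.correct for o in trace if o.stage == "transfer"]
    if not acq or not tra:
        raise ValueError("trace must contain both acquisition and transfer trials")
    return float(np.mean(acq)), float(np.mean(tra))


@dataclass(frozen=True)
class SweepGrid:
    """The two-condition sweep design: strengths × learning rates × groups."""

    strengths: tuple[int, ...] = (0,)
    learning_rates: tuple[float, ...] = DEFAULT_LEARNING_RATES
    groups: tuple[str, ...] = GROUPS
    replicates: int = 30
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not self.strengths or any(s not in range(5) for s in self.strengths):
            raise ConfigurationError("strengths must be a non-empty subset of 0..4")
        if not self.learning_rates or any(
            not 0.0 <= e <= 1.0 for e in self.learning_rates
        ):
            raise ConfigurationError("learning rates must lie in [0, 1]")
        if any(g not in GROUPS for g in self.groups):
            raise ConfigurationError(f"groups must be a subset of {GROUPS}")


@dataclass
class SweepResult:
    """Per-cell means of both metrics over replicates (tidy long format)."""

    frame: pd.DataFrame
    grid: SweepGrid

    def cell(self, group: str, strength: int, learning_rate: float) -> pd.Series:
        f = self.frame
        match = f[
            (f["group"] == group)
            & (f["strength"] == strength)
            & (np.isclose(f["learning_rate"], learning_rate))
        ]
        if len(match) != 1:
            raise KeyError((group, strength, learning_rate))
        return match.iloc[0]


def _session_metrics(
    profile: SubjectProfile,
    agent_config: AgentConfig,
    strength: int,
    epsilon: float,
    seed: int,
    trials_per_block: int,
    task_kwargs: Mapping[str, bool],
) -> tuple[float, float, bool, float, float]:
    counts = trials_from_profile(profile, trials_per_block)
    task_seed = int(substream(seed, "task-seed").integers(2**31))
    trials = build_task_from_counts(counts, task_seed, **task_kwargs)
    agent = Agent(
        AgentConfig(
            epsilon=epsilon,
            beta_gain=agent_config.beta_gain,
            actor_modulator=agent_config.actor_modulator,
            baseline_decay=agent_config.baseline_decay,
            coupling_gain=agent_config.coupling_gain,
            hippocampus_lr=agent_config.hippocampus_lr,
        ),
        strength,
    )
    trace = run_session(agent, trials, substream(seed, "agent"))
    fr = firing_rate_percent(trace)
    wu, degenerate = weight_update_percent(trace)
    acq, tra = accuracy_by_phase(trace)
    return fr, wu, degenerate, acq, tra


def run_condition(
    grid: SweepGrid,
    profiles: Mapping[str, Sequence[SubjectProfile]],
    agent_config: AgentConfig | None = None,
    trials_per_block: int = 8,
    **task_kwargs: bool,
) -> SweepResult:
    """Run one sweep condition over the full (group × strength × ε) grid.

    Each cell runs ``grid.replicates`` sessions; replicate ``i`` takes its
    per-stage trial counts from the group's profiles, cycling through them.
    Deterministic given ``grid.base_seed``.
    """
    agent_config = agent_config or AgentConfig()
    for group in grid.groups:
        if not profiles.get(group):
            raise ConfigurationError(f"no subject profiles for group {group!r}")
    rows = []
    for group in grid.groups:
        group_profiles = list(profiles[group])
        for strength in grid.strengths:
            for eps in grid.learning_rates:
                fr, wu, deg, acq, tra = [], [], [], [], []
                for rep in range(grid.replicates):
                    profile = group_profiles[rep % len(group_profiles)]
                    seed = int(
                        substream(
                            grid.base_seed,
                            "sweep",
                            group,
                            f"s{strength}",
                            f"e{eps:.3f}",
                            f"r{rep}",
                        ).integers(2**31)
                    )
                    f, w, d, a, t = _session_metrics(
                        profile, agent_config, strength, float(eps), seed,
                        trials_per_block, task_kwargs,
                    )
                    fr.append(f)
                    wu.append(w)
                    deg.append(d)
                    acq.append(a)
                    tra.append(t)
                rows.append(
                    {
                        "group": group,
                        "strength": strength,
                        "learning_rate": float(eps),
                        "firing_rate_pct": float(np.mean(fr)),
                        "firing_rate_sd": float(np.std(fr, ddof=1)) if len(fr) > 1 else 0.0,
                        "weight_update_pct": float(np.mean(wu)),
                        "weight_update_sd": float(np.std(wu, ddof=1)) if len(wu) > 1 else 0.0,
                        "weight_update_degenerate": bool(all(deg)),
                        "accuracy_acquisition": float(np.mean(acq)),
                        "accuracy_transfer": float(np.mean(tra)),
                        "n_replicates": grid.replicates,
                    }
                )
    return SweepResult(frame=pd.DataFrame(rows), grid=grid)


def summarize_table(result: SweepResult) -> dict[str, pd.DataFrame]:
    """Four-panel summary: groups × learning-rate columns per metric.

    Panels ``A``/``B`` hold firing-rate / weight-update means at strength 0;
    panels ``C``/``D`` the same metrics at strengths 1–4 (one row per group
    and strength).  Raises if any requested grid cell is missing.
    """
    f = result.frame
    grid = result.grid
    missing = [
        (g, s, e)
        for g in grid.groups
        for s in grid.strengths
        for e in grid.learning_rates
        if f[
            (f["group"] == g)
            & (f["strength"] == s)
            & (np.isclose(f["learning_rate"], e))
        ].empty
    ]
    if missing:
        raise ConfigurationError(f"incomplete sweep grid; missing cells: {missing}")

    def panel(metric: str, strengths: Sequence[int]) -> pd.DataFrame:
        sub = f[f["strength"].isin(strengths)]
        table = sub.pivot_table(
            index=["group", "strength"], columns="learning_rate", values=metric
        )
        return table.sort_index()

    zero = [s for s in grid.strengths if s == 0]
    pos = [s for s in grid.strengths if s > 0]
    panels: dict[str, pd.DataFrame] = {}
    if zero:
        panels["A"] = panel("firing_rate_pct", zero)
        panels["B"] = panel("weight_update_pct", zero)
    if pos:
        panels["C"] = panel("firing_rate_pct", pos)
        panels["D"] = panel("weight_update_pct", pos)
    return panels
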