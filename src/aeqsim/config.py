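"""Run configuration: a validated YAML/JSON schema for reproducible runs."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .task import STAGES

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; message names the bad key."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskBlock(_Block):
    trials_per_block: int = Field(8, ge=1)
    blocks_per_stage: dict[str, float] = {
        "shaping": 4,
        "equivalence_training": 4,
        "new_consequent": 4,
        "transfer": 2,
    }
    transfer_feedback: bool = False
    transfer_includes_trained: bool = False


class AgentBlock(_Block):
    epsilon: float = Field(0.1, ge=0.0, le=1.0)
    beta_gain: float = Field(1.0, gt=0.0)
    actor_modulator: Literal["reward_baseline", "prediction_error"] = "reward_baseline"
    baseline_decay: float = Field(0.1, gt=0.0, le=1.0)
    coupling_gain: float = Field(0.5, ge=0.0)
    hippocampus_lr: float | None = Field(None, ge=0.0)


class SweepBlock(_Block):
    strengths: list[int] = [0]
    learning_rates: list[float] = [round(0.1 * i, 1) for i in range(11)]
    replicates: int = Field(30, ge=1)


class CohortBlock(_Block):
    n_per_group: int = Field(5, ge=1)
    block_means: dict[str, float] = {
        "shaping": 4.0,
        "equivalence_training": 4.0,
        "new_consequent": 4.0,
        "transfer": 2.0,
    }
    block_sd: float = Field(0.5, ge=0.0)
    accuracy_acquisition: float = Field(0.82, ge=0.5, le=1.0)
    accuracy_transfer: float = Field(0.78, ge=0.5, le=1.0)
    accuracy_sd: float = Field(0.06, ge=0.0)
    impairment: float = Field(0.0, ge=0.0, le=0.5)


class RunConfig(_Block):
    """Top-level run configuration; every field has a sensible default."""

    task: TaskBlock = TaskBlock()
    agent: AgentBlock = AgentBlock()
    sweep: SweepBlock = SweepBlock()
    cohort: CohortBlock = CohortBlock()
    out_dir: str = "aeqsim-out"
    seed: int = 0
    log_level: str = "INFO"


def _check_stages(cfg: RunConfig) -> None:
    for mapping, origin in (
        (cfg.task.blocks_per_stage, "task.blocks_per_stage"),
        (cfg.cohort.block_means, "cohort.block_means"),
    ):
        unknown = set(mapping) - set(STAGES)
        if unknown:
            raise ConfigError(f"{origin}: unknown stage(s) {sorted(unknown)}")
        for stage in STAGES:
            if mapping.get(stage, 0) <= 0:
                raise ConfigError(f"{origin}.{stage}: must be a positive count")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing file fields default.

    ``None`` or an empty file yields the all-defaults configuration.
    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as err:
        first = err.errors()[0]
        key = ".".join(str(part) for part in first["loc"])
        raise ConfigError(f"invalid config at {key or '<root>'}: {first['msg']}") from err
    _check_stages(cfg)
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialise a config back to YAML; round-trips through load."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)
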