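"""Two-module connectionist learner: hippocampus + basal ganglia.

The basal-ganglia module is a trial-by-trial Rescorla–Wagner reward
predictor plus a direct actor.  The actor holds a 2×16 action-value matrix
``M`` (actions left/right × the 16 antecedent-consequent input
combinations); on each trial the value of an action is the entry for the
association displayed on that action's side, choice is softmax with slope
``beta``, and chosen/unchosen entries move by the policy-gradient step
``epsilon * (delta_a,a' - P[a']) * modulator`` where the modulator is either
reward-minus-baseline or the Rescorla–Wagner prediction error (both forms
supported, see :class:`AgentConfig`).

The hippocampus module is a patch-coded stimulus representation: 10 patches
of 2 nodes (20 nodes).  Eight patches code the eight trained/novel
associations, two code the antecedent families; each patch's two nodes code
the left/right choice and compete by winner-take-all.  The winning nodes add
a strength-scaled bias to the corresponding action values (the one-to-one
coupling to the basal ganglia), and their weights move by a
softmax-probability step after feedback.  Hippocampus strength 0 silences
the module and sets beta = 0, which forces chance behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .task import (
    TrialSpec,
    bit_index,
    encode_trial,
    give_feedback,
)

__all__ = [
    "PATCH_ASSOCIATIONS",
    "AgentConfig",
    "HippocampusState",
    "BasalGangliaState",
    "TrialOutcome",
    "Agent",
    "softmax_probabilities",
    "choose_action",
    "beta_schedule",
    "winner_take_all",
    "rescorla_wagner_update",
    "direct_actor_update",
    "policy_actor_update",
    "expected_average_reward",
    "hippocampus_update",
    "run_session",
]

_PROB_TOL = 1e-9

# Patch layout: 8 association patches (the 6 trained + 2 novel pairs) then
# 2 antecedent-family patches.  Node index = 2 * patch + side (0 left, 1 right).
PATCH_ASSOCIATIONS: tuple[tuple[str, str], ...] = (
    ("A1", "X1"),
    ("A2", "X1"),
    ("B1", "Y1"),
    ("B2", "Y1"),
    ("A1", "X2"),
    ("B1", "Y2"),
    ("A2", "X2"),
    ("B2", "Y2"),
)
N_PATCHES = 10
N_NODES = 2 * N_PATCHES

_PAIR_PATCH = {pair: i for i, pair in enumerate(PATCH_ASSOCIATIONS)}
_FAMILY_PATCH = {"A": 8, "B": 9}


def softmax_probabilities(m_l: float, m_r: float, beta: float) -> tuple[float, float]:
    """Softmax choice probabilities (p_left, p_right) with slope ``beta``.

    Computed with max-subtraction so it is stable for |beta * m| well past
    the float overflow point of a naive exponential.
    """
    if not np.isfinite(beta) or beta < 0:
        raise ValueError(f"beta must be finite and >= 0, got {beta!r}")
    zl, zr = beta * m_l, beta * m_r
    top = max(zl, zr)
    el, er = np.exp(zl - top), np.exp(zr - top)
    total = el + er
    return float(el / total), float(er / total)


def choose_action(p_left: float, p_right: float, rng: np.random.Generator) -> str:
    """Sample 'left'/'right' with the given probabilities."""
    if abs(p_left + p_right - 1.0) > _PROB_TOL:
        raise ValueError("choice probabilities must sum to 1")
    return "right" if rng.random() < p_right else "left"


def beta_schedule(strength: int, beta_gain: float = 1.0) -> float:
    """Softmax slope as a linear function of hippocampus strength."""
    if strength not in (0, 1, 2, 3, 4):
        raise ValueError(f"hippocampus strength must be in 0..4, got {strength!r}")
    return beta_gain * strength


def winner_take_all(activations: Sequence[float], rng: np.random.Generator) -> int:
    """Index of the maximally active node; ties broken uniformly at random."""
    act = np.asarray(activations, dtype=float)
    if act.size == 0:
        raise ValueError("winner_take_all needs a non-empty patch")
    winners = np.flatnonzero(act == act.max())
    if winners.size == 1:
        return int(winners[0])
    return int(winners[rng.integers(winners.size)])


def rescorla_wagner_update(
    w: np.ndarray, u: np.ndarray, r: float, epsilon: float
) -> tuple[np.ndarray, float]:
    """One delta-rule step: w -> w + epsilon * delta * u, delta = r - v.

    The reward prediction v is the dot product of ``w`` with the active
    components of the binary input ``u``.  Returns the new weights and delta.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"learning rate must be in [0, 1], got {epsilon!r}")
    u = np.asarray(u, dtype=float)
    v = float(w @ u)
    delta = r - v
    return w + epsilon * delta * u, delta


def direct_actor_update(
    M: np.ndarray,
    action_bits: tuple[int, int],
    action: int,
    modulator: float,
    epsilon: float,
    p: tuple[float, float],
) -> np.ndarray:
    """Policy-gradient step on the action matrix.

    ``action_bits[a]`` is the input component read by action ``a`` on this
    trial (the association shown on that side); only those two entries move.
    The per-action coefficients (1 - P[a]) for the chosen and (0 - P[a'])
    for the unchosen action sum to zero exactly.
    """
    if abs(p[0] + p[1] - 1.0) > _PROB_TOL:
        raise ValueError("choice probabilities must be normalised")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"learning rate must be in [0, 1], got {epsilon!r}")
    out = M.copy()
    for a in (0, 1):
        kron = 1.0 if a == action else 0.0
        out[a, action_bits[a]] += epsilon * (kron - p[a]) * modulator
    return out


def policy_actor_update(
    m_r: float,
    m_l: float,
    action: str,
    r_a: float,
    r_bar: float,
    epsilon: float,
    p: tuple[float, float],
) -> tuple[float, float]:
    """Scalar policy-actor step on (m_r, m_l).

    m_r += eps * (kron(a, r) - P[r]) * (r_a - r_bar) and symmetrically for
    m_l; stochastic gradient ascent on the average reward for any baseline.
    """
    p_l, p_r = p
    if abs(p_l + p_r - 1.0) > _PROB_TOL:
        raise ValueError("choice probabilities must be normalised")
    kron_r = 1.0 if action == "right" else 0.0
    kron_l = 1.0 - kron_r
    mod = r_a - r_bar
    return m_r + epsilon * (kron_r - p_r) * mod, m_l + epsilon * (kron_l - p_l) * mod


def expected_average_reward(
    p: tuple[float, float], mean_r_left: float, mean_r_right: float
) -> float:
    """Probability-weighted mean reward <r> = P[l]<r_l> + P[r]<r_r>."""
    p_l, p_r = p
    if abs(p_l + p_r - 1.0) > _PROB_TOL:
        raise ValueError("choice probabilities must be normalised")
    return p_l * mean_r_left + p_r * mean_r_right


@dataclass
class HippocampusState:
    """Patch-coded stimulus layer: 20 node weights, softmax slope, strength."""

    strength: int
    beta: float
    weights: np.ndarray = field(default_factory=lambda: np.zeros(N_NODES))

    def __post_init__(self) -> None:
        if self.strength not in (0, 1, 2, 3, 4):
            raise ValueError("hippocampus strength must be in 0..4")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.strength == 0 and self.beta != 0.0:
            raise ValueError("beta must be 0 when strength is 0")
        if self.weights.shape != (N_NODES,):
            raise ValueError(f"expected {N_NODES} node weights")


@dataclass
class BasalGangliaState:
    """Rescorla–Wagner predictor plus direct-actor action values."""

    epsilon: float
    M: np.ndarray = field(default_factory=lambda: np.zeros((2, 16)))
    w: np.ndarray = field(default_factory=lambda: np.zeros(16))
    r_bar: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("learning rate must be in [0, 1]")


@dataclass(frozen=True)
class TrialOutcome:
    """Everything recorded about one simulated trial."""

    stage: str
    action: str
    p_left: float
    p_right: float
    reward: float | None
    delta: float | None
    correct: bool
    updating: bool
    correct_value_increased: bool | None
    winning_node: int


@dataclass(frozen=True)
class AgentConfig:
    """Tunable parameters of the learner.

    epsilon          basal-ganglia learning rate (the paper's swept input)
    beta_gain        softmax slope per unit of hippocampus strength
    actor_modulator  'reward_baseline' uses (r - r_bar); 'prediction_error'
                     uses the Rescorla–Wagner delta
    baseline_decay   step of the exponential running-mean reward baseline
    coupling_gain    scale of the hippocampal additive bias on action values
    hippocampus_lr   step scale of the hippocampal weight update; ``None``
                     ties it to epsilon so that epsilon = 0 freezes all
                     learning (the sweep's lr = 0 column stays at chance)
    """

    epsilon: float = 0.1
    beta_gain: float = 1.0
    actor_modulator: Literal["reward_baseline", "prediction_error"] = "reward_baseline"
    baseline_decay: float = 0.1
    coupling_gain: float = 0.5
    hippocampus_lr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.beta_gain <= 0:
            raise ValueError("beta_gain must be > 0")
        if not 0.0 < self.baseline_decay <= 1.0:
            raise ValueError("baseline_decay must be in (0, 1]")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        if self.actor_modulator not in ("reward_baseline", "prediction_error"):
            raise ValueError("unknown actor_modulator")


def _trial_patches(trial: TrialSpec) -> tuple[int, int]:
    """Active patches: the pair patch of the trained association on screen
    and the antecedent-family patch."""
    pair = _PAIR_PATCH[(trial.antecedent, trial.correct_option)]
    family = _FAMILY_PATCH[trial.antecedent[0]]
    return pair, family


def hippocampus_update(
    state: HippocampusState,
    trial: TrialSpec,
    action: str,
    reward: float,
    p_chosen: float,
    step: float,
) -> HippocampusState:
    """Move the winning nodes toward the chosen-and-rewarded association.

    In each active patch the node coding the chosen side gains (reward) or
    loses (no reward) ``step * (1 - p_chosen)``; all other nodes are
    untouched.  At strength 0 the module is silent and nothing moves.
    """
    if state.strength == 0 or step == 0.0:
        return state
    side = 0 if action == "left" else 1
    sign = 1.0 if reward > 0 else -1.0
    weights = state.weights.copy()
    for patch in _trial_patches(trial):
        weights[2 * patch + side] += step * (1.0 - p_chosen) * sign
    return replace(state, weights=weights)


class Agent:
    """A simulated subject: hippocampus + basal ganglia, run trial by trial."""

    def __init__(self, config: AgentConfig, strength: int):
        self.config = config
        self.hippocampus = HippocampusState(
            strength=strength, beta=beta_schedule(strength, config.beta_gain)
        )
        self.basal_ganglia = BasalGangliaState(epsilon=config.epsilon)

    @property
    def strength(self) -> int:
        return self.hippocampus.strength

    def _action_values(
        self, trial: TrialSpec, rng: np.random.Generator
    ) -> tuple[float, float, tuple[int, int], int]:
        """Per-trial action values (left, right), their input bits, and the
        winning hippocampal node of the association patch."""
        left_bit = bit_index(trial.antecedent, trial.left_option)
        right_bit = bit_index(trial.antecedent, trial.right_option)
        M = self.basal_ganglia.M
        m_l, m_r = float(M[0, left_bit]), float(M[1, right_bit])
        hip = self.hippocampus
        pair_patch, family_patch = _trial_patches(trial)
        pair_winner = 2 * pair_patch + winner_take_all(
            hip.weights[2 * pair_patch : 2 * pair_patch + 2], rng
        )
        if hip.strength > 0:
            scale = self.config.coupling_gain * hip.strength / 4.0
            family_winner = 2 * family_patch + winner_take_all(
                hip.weights[2 * family_patch : 2 * family_patch + 2], rng
            )
            for node in (pair_winner, family_winner):
                bias = scale * float(hip.weights[node])
                if node % 2 == 0:
                    m_l += bias
                else:
                    m_r += bias
        return m_l, m_r, (left_bit, right_bit), pair_winner

    def run_trial(self, trial: TrialSpec, rng: np.random.Generator) -> TrialOutcome:
        """Simulate one trial, updating all internal state in place.

        Event order: encode → softmax over biased action values → choose →
        feedback → Rescorla–Wagner update → actor update → hippocampus
        update → reward-baseline update.
        """
        cfg = self.config
        bg = self.basal_ganglia
        m_l, m_r, bits, winner = self._action_values(trial, rng)
        p_l, p_r = softmax_probabilities(m_l, m_r, self.hippocampus.beta)
        action = choose_action(p_l, p_r, rng)
        correct = action == trial.correct_side
        reward = give_feedback(trial, action)

        delta: float | None = None
        updating = reward is not None and cfg.epsilon > 0.0
        correct_value_increased: bool | None = None
        if reward is not None:
            u = encode_trial(trial, self.strength).task_bits
            new_w, delta = rescorla_wagner_update(bg.w, u, reward, cfg.epsilon)
            if updating:
                bg.w = new_w
                correct_bit = bits[0] if trial.correct_side == "left" else bits[1]
                correct_idx = 0 if trial.correct_side == "left" else 1
                before = bg.M[correct_idx, correct_bit]
                modulator = (
                    reward - bg.r_bar
                    if cfg.actor_modulator == "reward_baseline"
                    else delta
                )
                bg.M = direct_actor_update(
                    bg.M,
                    bits,
                    0 if action == "left" else 1,
                    modulator,
                    cfg.epsilon,
                    (p_l, p_r),
                )
                after = bg.M[correct_idx, correct_bit]
                step = cfg.epsilon if cfg.hippocampus_lr is None else cfg.hippocampus_lr
                self.hippocampus = hippocampus_update(
                    self.hippocampus,
                    trial,
                    action,
                    reward,
                    p_r if action == "right" else p_l,
                    step,
                )
                correct_value_increased = correct and after > before
            # Baseline bookkeeping happens on every feedback trial, even
            # with learning frozen.
            bg.r_bar += cfg.baseline_decay * (reward - bg.r_bar)

        return TrialOutcome(
            stage=trial.stage,
            action=action,
            p_left=p_l,
            p_right=p_r,
            reward=reward,
            delta=delta,
            correct=correct,
            updating=updating,
            correct_value_increased=correct_value_increased,
            winning_node=winner,
        )


def run_session(
    agent: Agent, trials: Sequence[TrialSpec], rng: np.random.Generator
) -> list[TrialOutcome]:
    """Run the agent through a full trial sequence."""
    return [agent.run_trial(t, rng) for t in trials]
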