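"""Learner: softmax choice, delta-rule, direct/policy actor, hippocampus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeqsim.agent import (
    Agent,
    AgentConfig,
    HippocampusState,
    beta_schedule,
    choose_action,
    direct_actor_update,
    expected_average_reward,
    hippocampus_update,
    policy_actor_update,
    rescorla_wagner_update,
    run_session,
    softmax_probabilities,
    winner_take_all,
)
from aeqsim.task import TrialSpec, build_task

finite = st.floats(-50, 50, allow_nan=False)


def make_trial(left="X1", right="Y1", correct="left", stage="shaping",
               antecedent="A1", feedback=True):
    return TrialSpec(stage=stage, antecedent=antecedent, left_option=left,
                     right_option=right, correct_side=correct, feedback=feedback)


class TestSoftmax:
    @given(m=finite, beta=st.floats(0, 20))
    @settings(derandomize=True, max_examples=50)
    def test_equal_values_give_even_odds(self, m, beta):
        p_l, p_r = softmax_probabilities(m, m, beta)
        assert p_l == pytest.approx(0.5) and p_r == pytest.approx(0.5)

    @given(m_l=finite, m_r=finite)
    @settings(derandomize=True, max_examples=50)
    def test_zero_slope_is_uniform(self, m_l, m_r):
        assert softmax_probabilities(m_l, m_r, 0.0) == (0.5, 0.5)

    @given(m_l=finite, m_r=finite, beta=st.floats(0, 20))
    @settings(derandomize=True, max_examples=100)
    def test_normalisation(self, m_l, m_r, beta):
        p_l, p_r = softmax_probabilities(m_l, m_r, beta)
        assert abs(p_l + p_r - 1.0) < 1e-12

    def test_log_odds_closed_form(self):
        # value gap ln 3 at slope 1 puts 3:1 odds on the larger value
        _, p_r = softmax_probabilities(0.0, math.log(3.0), 1.0)
        assert p_r == pytest.approx(0.75, abs=1e-12)
        direct = math.exp(math.log(3.0)) / (math.exp(math.log(3.0)) + math.exp(0.0))
        assert p_r == pytest.approx(direct)

    def test_stable_at_extreme_arguments(self):
        p_l, p_r = softmax_probabilities(-700.0, 700.0, 1.0)
        assert p_r == pytest.approx(1.0) and np.isfinite(p_l)

    def test_monotone_in_value_gap_and_slope(self):
        gaps = np.linspace(-3, 3, 13)
        probs = [softmax_probabilities(0.0, g, 1.0)[1] for g in gaps]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        betas = [0.5, 1.0, 2.0, 4.0]
        probs = [softmax_probabilities(0.0, 1.0, b)[1] for b in betas]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities(0.0, 1.0, -0.1)


class TestChooseAction:
    def test_certain_probability_is_deterministic(self, rng):
        assert all(choose_action(0.0, 1.0, rng) == "right" for _ in range(100))

    def test_sampling_frequency_within_binomial_bound(self):
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(choose_action(0.25, 0.75, rng) == "right" for _ in range(n))
        sigma = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * sigma

    def test_same_seed_same_sequence(self):
        seqs = [
            [choose_action(0.5, 0.5, np.random.default_rng(3)) for _ in range(1)]
            for _ in range(2)
        ]
        a = [choose_action(0.4, 0.6, np.random.default_rng(5)) for _ in range(50)]
        b = [choose_action(0.4, 0.6, np.random.default_rng(5)) for _ in range(50)]
        assert a == b and seqs[0] == seqs[1]

    def test_unnormalised_probabilities_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_action(0.6, 0.6, rng)


class TestBetaSchedule:
    def test_strength_zero_forces_chance(self):
        assert beta_schedule(0, 1.0) == 0.0
        assert softmax_probabilities(-3.0, 9.0, beta_schedule(0)) == (0.5, 0.5)

    def test_linear_and_strictly_increasing(self):
        betas = [beta_schedule(s, 1.0) for s in range(5)]
        assert betas == [0.0, 1.0, 2.0, 3.0, 4.0]
        betas = [beta_schedule(s, 0.7) for s in range(5)]
        assert all(a < b for a, b in zip(betas, betas[1:]))


class TestWinnerTakeAll:
    def test_picks_maximum(self, rng):
        assert winner_take_all([0.2, 0.9], rng) == 1
        assert winner_take_all([5.0], rng) == 0

    def test_tie_break_uniform(self):
        rng = np.random.default_rng(11)
        n = 10_000
        counts = np.bincount(
            [winner_take_all([1.0, 1.0, 1.0], rng) for _ in range(n)], minlength=3
        )
        sigma = math.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(counts / n - 1 / 3) < 3 * sigma)

    def test_empty_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            winner_take_all([], rng)


class TestRescorlaWagner:
    def test_absent_stimulus_no_update(self):
        w = np.arange(4.0)
        w2, delta = rescorla_wagner_update(w, np.zeros(4), 1.0, 0.3)
        assert np.array_equal(w2, w) and delta == 1.0

    def test_zero_error_equilibrium(self):
        w = np.array([0.5, 0.5])
        w2, delta = rescorla_wagner_update(w, np.array([1, 1]), 1.0, 0.2)
        assert delta == 0.0 and np.array_equal(w2, w)

    def test_one_step_arithmetic(self):
        w2, delta = rescorla_wagner_update(np.zeros(3), np.array([0, 1, 0]), 1.0, 0.5)
        assert delta == 1.0
        assert np.array_equal(w2, np.array([0.0, 0.5, 0.0]))

    def test_learning_rate_bounds(self):
        with pytest.raises(ValueError):
            rescorla_wagner_update(np.zeros(2), np.ones(2), 1.0, 1.5)

    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0])
    def test_equilibrium_tracks_reward_probability(self, q):
        """Running mean of delta goes to ~0 and w settles about q."""
        rng = np.random.default_rng(17)
        w = np.zeros(1)
        u = np.ones(1)
        deltas, tail = [], []
        for t in range(2000):
            r = float(rng.random() < q)
            w, d = rescorla_wagner_update(w, u, r, 0.05)
            deltas.append(d)
            if t >= 1500:
                tail.append(w[0])
        assert abs(np.mean(deltas[-500:])) < 0.1
        assert abs(np.mean(tail) - q) < 0.1


class TestDirectActor:
    BITS = (3, 7)

    def test_zero_learning_rate_no_change(self):
        M = np.random.default_rng(0).normal(size=(2, 16))
        out = direct_actor_update(M, self.BITS, 0, 0.8, 0.0, (0.4, 0.6))
        assert np.array_equal(out, M)

    def test_reward_at_baseline_no_change(self):
        M = np.zeros((2, 16))
        out = direct_actor_update(M, self.BITS, 1, 0.0, 0.5, (0.3, 0.7))
        assert np.array_equal(out, M)

    @pytest.mark.parametrize("p_r", np.linspace(0.01, 0.99, 9))
    @pytest.mark.parametrize("action", [0, 1])
    def test_coefficients_sum_to_zero(self, p_r, action):
        """(1 - P[a]) + (0 - P[other]) = 0 exactly, for any modulator."""
        M = np.zeros((2, 16))
        out = direct_actor_update(M, self.BITS, action, 0.37, 0.5, (1 - p_r, p_r))
        applied = out - M
        coefficients = applied[0, self.BITS[0]] + applied[1, self.BITS[1]]
        assert coefficients == pytest.approx(0.0, abs=1e-15)

    def test_unnormalised_probabilities_rejected(self):
        with pytest.raises(ValueError):
            direct_actor_update(np.zeros((2, 16)), self.BITS, 0, 1.0, 0.5, (0.7, 0.7))


class TestPolicyActor:
    def test_one_step_arithmetic(self):
        m_r, m_l = policy_actor_update(0.0, 0.0, "right", 1.0, 0.0, 0.1, (0.5, 0.5))
        assert m_r == pytest.approx(0.05) and m_l == pytest.approx(-0.05)

    def test_reward_at_baseline_no_change(self):
        assert policy_actor_update(0.2, -0.1, "left", 0.7, 0.7, 0.5, (0.5, 0.5)) == (
            0.2,
            -0.1,
        )

    def test_rewarded_choice_probability_grows_monotonically(self):
        m_r = m_l = 0.0
        probs = []
        for _ in range(100):
            p_l, p_r = softmax_probabilities(m_l, m_r, 1.0)
            probs.append(p_r)
            m_r, m_l = policy_actor_update(m_r, m_l, "right", 1.0, 0.0, 0.1, (p_l, p_r))
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 0.9

    def test_reduces_to_direct_actor_on_shared_component(self):
        M = np.zeros((2, 16))
        bits = (5, 5)
        p = (0.35, 0.65)
        out = direct_actor_update(M, bits, 1, 1.0 - 0.2, 0.3, p)
        m_r, m_l = policy_actor_update(0.0, 0.0, "right", 1.0, 0.2, 0.3, p)
        assert out[1, 5] == pytest.approx(m_r) and out[0, 5] == pytest.approx(m_l)


class TestExpectedReward:
    def test_degenerate_policies(self):
        assert expected_average_reward((0.0, 1.0), 0.3, 0.9) == 0.9
        assert expected_average_reward((0.5, 0.5), 1.0, 0.0) == 0.5

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(23)
        p = (0.3, 0.7)
        mr, ml = 0.8, 0.2
        n = 100_000
        choices = rng.random(n) < p[1]
        rewards = np.where(
            choices, rng.random(n) < mr, rng.random(n) < ml
        ).astype(float)
        expected = expected_average_reward(p, ml, mr)
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(rewards.mean() - expected) < 3 * sigma


class TestHippocampus:
    def test_saturated_choice_zero_step(self):
        state = HippocampusState(strength=2, beta=2.0)
        out = hippocampus_update(state, make_trial(), "left", 1.0, 1.0, 0.5)
        assert np.array_equal(out.weights, state.weights)

    def test_silent_at_strength_zero(self):
        state = HippocampusState(strength=0, beta=0.0)
        out = hippocampus_update(state, make_trial(), "left", 1.0, 0.5, 0.5)
        assert out is state

    def test_losing_nodes_untouched(self):
        state = HippocampusState(strength=3, beta=3.0)
        out = hippocampus_update(state, make_trial(), "right", 1.0, 0.4, 0.5)
        moved = np.flatnonzero(out.weights != state.weights)
        assert all(node % 2 == 1 for node in moved)  # only right-side nodes

    def test_repeated_reward_makes_winner_dominant(self):
        """200 rewarded repetitions of one fixed-side pair: the reinforced
        node ends strictly above its patch sibling."""
        agent = Agent(AgentConfig(epsilon=0.2), strength=3)
        trial = make_trial()  # A1: X1 left (correct), fixed side
        rng = np.random.default_rng(5)
        for _ in range(200):
            agent.run_trial(trial, rng)
        weights = agent.hippocampus.weights
        assert weights[0] > weights[1]  # pair patch (A1,X1): left beats right

    def test_beta_zero_required_at_strength_zero(self):
        with pytest.raises(ValueError):
            HippocampusState(strength=0, beta=1.0)


BLOCKS = {"shaping": 2, "equivalence_training": 2, "new_consequent": 2, "transfer": 1}


class TestRunTrial:
    def test_frozen_agent_only_baseline_moves(self):
        agent = Agent(AgentConfig(epsilon=0.0), strength=0)
        before_M = agent.basal_ganglia.M.copy()
        before_w = agent.basal_ganglia.w.copy()
        rng = np.random.default_rng(0)
        outcomes = [agent.run_trial(make_trial(), rng) for _ in range(200)]
        assert np.array_equal(agent.basal_ganglia.M, before_M)
        assert np.array_equal(agent.basal_ganglia.w, before_w)
        assert agent.basal_ganglia.r_bar != 0.0
        acc = np.mean([o.correct for o in outcomes])
        assert abs(acc - 0.5) < 3 * math.sqrt(0.25 / 200)

    def test_probe_trial_changes_nothing_but_baseline_is_kept(self):
        agent = Agent(AgentConfig(epsilon=0.5), strength=2)
        probe = make_trial(stage="transfer", feedback=False)
        before = (
            agent.basal_ganglia.M.copy(),
            agent.basal_ganglia.w.copy(),
            agent.basal_ganglia.r_bar,
            agent.hippocampus.weights.copy(),
        )
        out = agent.run_trial(probe, np.random.default_rng(0))
        assert out.reward is None and not out.updating
        assert np.array_equal(agent.basal_ganglia.M, before[0])
        assert np.array_equal(agent.basal_ganglia.w, before[1])
        assert agent.basal_ganglia.r_bar == before[2]
        assert np.array_equal(agent.hippocampus.weights, before[3])

    def test_full_trace_bit_identical_across_runs(self):
        trials = build_task(BLOCKS, trials_per_block=8, seed=2)
        traces = []
        for _ in range(2):
            agent = Agent(AgentConfig(epsilon=0.4), strength=3)
            traces.append(run_session(agent, trials, np.random.default_rng(99)))
        assert traces[0] == traces[1]


class TestHandUnrolledTranscript:
    """Two-trial oracle: every state update matches explicit arithmetic."""

    def test_two_trial_transcript(self, scripted_rng_cls):
        cfg = AgentConfig(epsilon=0.5, beta_gain=1.0, coupling_gain=0.5,
                          baseline_decay=0.1)
        agent = Agent(cfg, strength=2)
        rng = scripted_rng_cls(randoms=[0.9, 0.3], integers=[0, 0])

        # Trial 1: A1 with X1 (left, correct) vs Y1.  All weights zero, so
        # both patch winner-take-alls tie (scripted to node 0) and the
        # softmax is even; the scripted 0.9 draw picks left -> rewarded.
        t1 = make_trial()
        out1 = agent.run_trial(t1, rng)
        assert out1.action == "left" and out1.correct
        assert (out1.p_left, out1.p_right) == (0.5, 0.5)
        assert out1.delta == 1.0  # prediction was 0
        # RW: both active components move by eps*delta = 0.5
        assert agent.basal_ganglia.w[0] == 0.5   # (A1,X1)
        assert agent.basal_ganglia.w[2] == 0.5   # (A1,Y1)
        # actor: modulator r - r_bar = 1; chosen left bit +0.25, right -0.25
        assert agent.basal_ganglia.M[0, 0] == 0.25
        assert agent.basal_ganglia.M[1, 2] == -0.25
        assert out1.correct_value_increased
        # hippocampus: left nodes of pair patch 0 and family patch 8 move by
        # eps*(1 - p_chosen) = 0.25
        assert agent.hippocampus.weights[0] == 0.25
        assert agent.hippocampus.weights[16] == 0.25
        assert agent.basal_ganglia.r_bar == pytest.approx(0.1)

        # Trial 2: same pair, sides swapped (X1 right, correct right).  The
        # trained left-coding nodes now bias the wrong side.
        t2 = make_trial(left="Y1", right="X1", correct="right")
        scale = cfg.coupling_gain * 2 / 4.0
        m_l = 2 * scale * 0.25      # both winning nodes bias left
        p_l = math.exp(2 * m_l) / (math.exp(2 * m_l) + 1.0)  # beta = 2
        p_r = 1.0 - p_l
        out2 = agent.run_trial(t2, rng)
        assert out2.p_left == pytest.approx(p_l)
        assert out2.p_right == pytest.approx(p_r)
        assert out2.action == "right" and out2.correct  # 0.3 < p_r
        assert out2.delta == 0.0  # v = w[0] + w[2] = 1 = r
        assert agent.basal_ganglia.w[0] == 0.5  # delta 0: no RW movement
        # actor: modulator = 1 - 0.1 = 0.9 on the swapped-side bits
        assert agent.basal_ganglia.M[1, 0] == pytest.approx(0.5 * (1 - p_r) * 0.9)
        assert agent.basal_ganglia.M[0, 2] == pytest.approx(-0.5 * p_l * 0.9)
        assert out2.correct_value_increased
        # hippocampus reinforces the right-coding nodes this time
        assert agent.hippocampus.weights[1] == pytest.approx(0.5 * (1 - p_r))
        assert agent.hippocampus.weights[17] == pytest.approx(0.5 * (1 - p_r))
        assert agent.basal_ganglia.r_bar == pytest.approx(0.19)


class TestBetaLimits:
    def test_large_beta_deterministic_choice(self):
        agent = Agent(AgentConfig(epsilon=0.0, beta_gain=200.0), strength=4)
        agent.basal_ganglia.M[0, 0] = 1.0  # left action strictly better
        rng = np.random.default_rng(0)
        outs = [agent.run_trial(make_trial(), rng) for _ in range(100)]
        assert all(o.action == "left" for o in outs)

    def test_zero_beta_chance_accuracy(self):
        trials = build_task(BLOCKS, trials_per_block=8, seed=4) * 10
        agent = Agent(AgentConfig(epsilon=0.5), strength=0)
        outs = run_session(agent, trials, np.random.default_rng(21))
        acc = np.mean([o.correct for o in outs])
        assert abs(acc - 0.5) < 3 * math.sqrt(0.25 / len(trials))
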