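# aeqsim

A connectionist simulator of **acquired-equivalence associative learning**:
a reinforcement-learning agent with interacting hippocampus and
basal-ganglia modules performs a two-alternative forced-choice task in
which faces (antecedents A1, A2, B1, B2) are paired with coloured fish
(consequents X1, X2, Y1, Y2), and the interaction of the two modules is
probed by sweeping hippocampus strength against the basal-ganglia learning
rate.

The package is aimed at computational cognitive neuroscientists who want a
small, fully reproducible model of hippocampus–basal ganglia interaction in
associative learning, including the group-comparison statistics used with
very small clinical samples (five patients versus five controls).

## The task

Acquisition (all with corrective feedback): *shaping* trains A1→X1 and
B1→Y1; *equivalence training* trains A2→X1 and B2→Y1, so A2/B2 acquire
equivalence with A1/B1 through the shared consequents; *new consequent*
trains A1→X2 and B1→Y2. The *transfer* phase then probes the never-trained
pairings A2→X2 and B2→Y2 implied by the acquired equivalence, with feedback
withheld.

## The model

* **Basal ganglia** — a trial-by-trial Rescorla–Wagner reward predictor,
  `w ← w + ε δ u` with prediction error `δ = r − υ`, `υ = w·u` over the 16
  binary face×fish input components, plus a **direct actor**: a 2×16
  action-value matrix `M` updated by the policy-gradient step
  `m_a' ← m_a' + ε (δ_aa' − P[a']) (r_a − r̄)` (a prediction-error-modulated
  variant is available). The learning rate ε is the "basal-ganglia input"
  swept in the experiments.
* **Hippocampus** — a patch-coded stimulus layer of 10 patches × 2 nodes
  with winner-take-all competition inside each patch; winning nodes add a
  strength-scaled bias to the action values (the one-to-one coupling) and
  are updated by a softmax-probability step `ε (1 − P[chosen])`. The
  integer **hippocampus strength** 0–4 is thermometer-coded and sets the
  softmax slope β = strength; strength 0 silences the module and forces
  chance behaviour.
* **Choice** — softmax over the two action values,
  `P[r] = e^{βm_r} / (e^{βm_r} + e^{βm_l})`.

Two session-level summary metrics anchor at 50% for a chance-level agent:
the **firing-rate %** (trials on which the winner-take-all output matched
the rewarded side) and the **weight-update %** (updating trials on which
the correct action's value increased).

Synthetic subject cohorts (patient/control, five per group by default)
supply the per-stage block averages that size each simulated session and
per-phase accuracies for the behavioural group comparison, which uses an
**exact** two-sided Mann–Whitney rank-sum test computed by complete
enumeration (the normal approximation is unreliable at n = m = 5).

## Worked example

```python
from aeqsim import (Agent, AgentConfig, build_task, run_session,
                    firing_rate_percent, weight_update_percent,
                    accuracy_by_phase)
from aeqsim._seeding import substream

blocks = {"shaping": 4, "equivalence_training": 4,
          "new_consequent": 4, "transfer": 2}
trials = build_task(blocks, trials_per_block=8, seed=0)   # 112 trials
agent = Agent(AgentConfig(epsilon=0.5), strength=3)
trace = run_session(agent, trials, substream(0, "demo"))
wu, _ = weight_update_percent(trace)
acq, tra = accuracy_by_phase(trace)
print(f"firing rate: {firing_rate_percent(trace):.1f}%  weight update: {wu:.1f}%")
print(f"acquisition accuracy: {acq:.3f}  transfer accuracy: {tra:.3f}")
```

prints

```
firing rate: 75.0%  weight update: 80.2%
acquisition accuracy: 0.802  transfer accuracy: 0.438
```

With hippocampus strength 3 and learning rate 0.5 the agent learns the
trained pairings well above chance (75% of choices land on the rewarded
side; 80% of basal-ganglia updates move the correct action's value up),
while the un-reinforced transfer probes stay near chance — the model's
generalization lives in the acquisition-phase equivalence structure, not in
feedback-free transfer.

The same runs are available from the shell:

```bash
aeqsim sweep --strengths 1,2,3,4 --replicates 30 --seed 7 --out out/
aeqsim behavior --seed 7 --out out/      # cohort accuracies + exact rank-sum
```

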