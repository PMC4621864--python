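# Methods

## Task environment

The task presents one antecedent (face) with two consequent options (fish),
one per side; the agent picks a side. Stage structure and trained pairs:

| stage                | pairs (antecedent → correct, foil) | feedback |
|----------------------|------------------------------------|----------|
| shaping              | A1→X1 (Y1), B1→Y1 (X1)             | yes      |
| equivalence_training | A2→X1 (Y1), B2→Y1 (X1)             | yes      |
| new_consequent       | A1→X2 (Y2), B1→Y2 (X2)             | yes      |
| transfer             | A2→X2 (Y2), B2→Y2 (X2)             | no (default) |

Within each block every active pair appears equally often and the correct
option's side is counterbalanced to 50% ± one trial per pair; order within
a block is shuffled. Reward is coded 1 (correct) / 0 (incorrect), which
makes the Rescorla–Wagner prediction υ interpretable as a probability of
reward and keeps the chance-level error dynamics symmetric. Feedback-free
probe trials return a no-reward marker and trigger no learning update.
Whether the transfer phase also re-presents trained (still-reinforced)
pairs is exposed as the `transfer_includes_trained` switch, off by default:
withholding the retest is the conservative reading of the task.

Stage lengths are fixed block counts taken from the subject profile; there
is no performance-criterion advancement. Input encoding: 16 binary
face×fish components indexed row-major (`4*antecedent + consequent` over
the orders A1,A2,B1,B2 / X1,X2,Y1,Y2), plus a 4-unit thermometer code of
the integer hippocampus strength 0–4.

## Learner

**Basal ganglia.** A linear reward predictor trained by the delta rule
`w ← w + ε δ u`, `δ = r − υ`, `υ = w·u`, and a direct actor over a 2×16
action-value matrix `M`. Actions are side choices; on a given trial the
value of an action is the `M` entry for the association displayed on that
action's side (left value reads `M[left, bit(antecedent, left_option)]`,
and symmetrically for right), and the actor update touches exactly those
two entries with coefficients `(1 − P[chosen])` and `(0 − P[unchosen])`,
which sum to zero exactly. Reading one side-specific component per action
— rather than summing both active components into each action value — is
required for the model to be able to learn at all under side
counterbalancing: a both-components read-out gives both actions identical
values on every trial, pinning behaviour at chance forever. The update's
modulator is reward minus baseline `(r − r̄)` by default, with the
prediction-error form (`δ`) available as `actor_modulator =
"prediction_error"`; both forms appear in the policy-gradient literature
and differ only in variance, not in the direction of the expected update.
The baseline `r̄` is an exponential running mean of reward (decay 0.1,
initialised at 0) and is updated on every feedback trial even when
learning is frozen. A scalar two-action variant of the same rule
(`policy_actor_update`) is provided and coincides with the matrix form on
a shared component.

**Hippocampus.** Ten patches of two nodes (20 nodes). Eight patches code
the eight trained/novel associations, two code the antecedent families
(A-side / B-side); each patch's two nodes code the left/right choice and
compete by winner-take-all (ties broken uniformly at random). The winning
nodes of the trial's two active patches add an additive bias
`coupling_gain · strength/4 · weight` to the corresponding action value —
this is the one-to-one coupling to the basal ganglia. After feedback the
winning-side node of each active patch moves by `step · (1 − P[chosen])`,
up when the choice was rewarded and down when it was not; losing nodes are
untouched. The hippocampal step is tied to the basal-ganglia learning rate
by default (`hippocampus_lr = None`), so a learning rate of zero freezes
the whole agent; it can be set independently.

**Choice.** Softmax with slope `β = beta_gain · strength` (gain default
1.0, linear in strength): strength 0 gives β = 0 and uniform random
choice; larger strengths sharpen choice toward the higher-valued action.
The softmax is computed with max-subtraction and is stable for arguments
far beyond `|β·m| = 700`. Linearity is the simplest schedule that anchors
the absent-hippocampus condition exactly at chance.

Event order within a trial: encode → winner-take-all → biased action
values → softmax → choice → feedback → delta-rule update → actor update →
hippocampus update → baseline update.

### Defaults and their rationale

| parameter        | default | meaning                                            |
|------------------|---------|----------------------------------------------------|
| `epsilon`        | swept   | basal-ganglia learning rate, in [0, 1]             |
| `beta_gain`      | 1.0     | softmax slope per unit strength                    |
| `coupling_gain`  | 0.5     | hippocampal bias scale on action values            |
| `baseline_decay` | 0.1     | running-mean reward step                           |
| `hippocampus_lr` | = ε     | hippocampal step scale                             |

All weights, action values and the baseline start at zero; no weight
clipping is applied. `coupling_gain` and the β schedule are declared
conventions (the coupling arithmetic has no canonical published form);
the coupling gain was fixed once at 0.5 after confirming the simulated
operating regime — chance anchoring near 50% with the hippocampus silent,
and a firing-rate plateau in the high-60s-to-70s with it active — and is
not tuned per experiment.

## Sweep metrics

* **firing-rate %** — 100 × (fraction of trials whose chosen action
  matched the rewarded side). The winner-take-all output of the network is
  the chosen action, so this reads out the model's "neural firing"
  alignment with the task.
* **weight-update %** — 100 × (fraction of updating trials on which the
  correct action's value increased). Sessions without updating trials
  (learning rate 0, or all-probe traces) are degenerate; they are reported
  at the 50% chance anchor with an explicit flag so that sweep grids
  containing the 0 column stay complete.

Both metrics are means over 30 replicate sessions per grid cell, with
replicate dispersion reported alongside. The two-condition design fixes
strength at 0 (condition 1) or sweeps it over 1–4 (condition 2), crossing
each with learning rates 0, 0.1, …, 1.0 for both groups.

## Synthetic subjects

Per-subject inputs the original behavioural study drew from participants —
average block counts per stage and per-phase accuracy — are not published,
so the cohort module generates synthetic stand-ins: truncated-normal draws
around group-level means, balanced patient/control groups (five per group
by default). Defaults: 4 blocks × 8 trials per acquisition stage and
2 × 8 transfer (112-trial sessions), block SD 0.5, accuracy means
0.82 (acquisition) / 0.78 (transfer), SD 0.06, truncated to [0.5, 1]. The
group difference defaults to zero, emulating the reported null finding; an
`impairment` parameter lowers the patient means for power studies and
produces rank-sum rejection rates that grow monotonically with the
decrement.

What the generator does **not** emulate: individual learning curves,
reaction times, IQ covariates, medication or seizure-history effects, and
any within-session non-stationarity of real subjects. Passing tests
therefore certify the simulator's internal behaviour under the stated
generative assumptions, not claims about real patient data.

## Statistics

Group comparisons use an exact two-sided Mann–Whitney rank-sum test:
midranks for ties, the statistic's null distribution obtained by complete
enumeration of all C(n+m, n) rank assignments (supported up to 20 total
observations; C(20,10) = 184 756). The two-sided p is the fraction of
assignments at least as far from the null mean n·m/2 as the observed
statistic. At n = m = 5 complete separation gives p = 2/252 ≈ 0.0079, the
smallest attainable two-sided level, which is why the exact form matters
at this sample size.

## Reproducibility

A single global seed fans out into named substreams via
`SeedSequence([seed, crc32(name), ...])`, so every component (task
shuffling, choice sampling, cohort draws, each sweep cell × replicate) has
an independent, stable stream and adding a component never perturbs
existing ones. Identical configuration + seed reproduces output files
byte-for-byte; each CLI run writes a manifest (config hash, seed, library
versions).

## Problem sizes

The sweep used throughout the tests and the acceptance script is 2 groups
× 11 learning rates × 30 replicates of 112-trial sessions per strength
(660 sessions for condition 1, 2 640 for condition 2), which keeps a full
two-condition run under a minute on one CPU while holding the Monte-Carlo
standard error of each cell mean near half a percentage point.

## Known limitations

* Transfer-probe behaviour is at chance by construction when feedback is
  withheld and the novel-pair action values start at zero: the model's
  acquired equivalence is expressed through the shared-consequent training
  structure, not as spontaneous above-chance transfer choice.
* The hippocampal patch nodes code left/right choice, so under side
  counterbalancing their weights carry little stimulus information; the
  functional effect of hippocampus strength is dominated by the softmax
  slope schedule and the coupling bias acts as a small state-dependent
  perturbation.
* Temporal-difference learning and eligibility traces are deliberately out
  of scope; the actor is a static-choice policy-gradient learner with
  immediate reward.
* Exact rank-sum enumeration is limited to 20 observations; larger cohorts
  would need the network/recursive null distribution or the asymptotic
  test.
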