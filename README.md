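# twostep

Simulation, hierarchical model fitting and neural population analysis for a
mouse **two-step decision task with transition-probability reversals**.

## The scientific problem

In the two-step task a first-step choice (top vs bottom poke) leads
probabilistically — commonly with P = 0.8, rarely with P = 0.2 — to a
left-active or right-active second-step state where a probabilistic water
reward is delivered.  Reward probabilities (good/neutral/bad = 0.8/0.4/0.2)
and the action→state transition probabilities both reverse in blocks, with
block transitions triggered by the subject's own behaviour: an exponential
moving average (τ = 8 trials) of correct choices crossing a 75% threshold,
followed by a 20-trial delay (neutral blocks end by a per-trial hazard of 0.1
after trial 40, giving 50-trial mean length).  Because both reward and
transition contingencies change, *model-based* control (planning through
learned transition probabilities) and *model-free* control (caching action
values) make dissociable predictions about how trial events drive subsequent
choices.

This package re-implements that full analysis pipeline as a tested library
driven entirely by synthetic data:

- **`twostep.task`** — the two-step and probabilistic reversal-learning
  environments, including behaviour-triggered block transitions and the
  1-in-6 optogenetic stimulation schedule.
- **`twostep.agents`** — the 14-parameter RL model family.  Net action
  values are Q_net(c) = G_mf·Q_mf(c) + G_mo·Q_mo(c, s_prev) + G_mb·Q_mb(c) +
  X(c), with Q_mb(c) = Σ_s P(s|c)V(s), eligibility-trace updates
  Q_mf(c) ← (1−α_Q)Q_mf(c) + α_Q(λr + (1−λ)V(s)), forgetting of unchosen
  actions/unvisited states, multi-trial choice and motor perseveration, and a
  softmax decision rule.  The same engine simulates choices and scores
  observed sessions (the likelihood is a numba kernel).
- **`twostep.hierfit`** — hierarchical Bayesian fitting of any per-unit
  likelihood by Expectation-Maximization with a Laplace E-step
  (h_i ~ N(μ, Σ), Σ diagonal, in transformed parameter space), and iBIC
  model comparison: −½ iBIC = log p(D|θ_ML) − ½|M| log|D| with the marginal
  likelihood Monte-Carlo averaged over K prior samples.
- **`twostep.behavior`** — stay probabilities, hierarchical logistic
  regressions of choice (one-trial-back and lagged trial-history designs
  with ±0.5 predictor codings), reversal-curve exponential fits,
  trial-shuffling permutation tests for stimulation effects, subject
  bootstrap tests, and cross-subject effect regressions.
- **`twostep.neural`** — trial alignment by linear time warping of the
  choice→outcome interval to the session median (20 Hz grid, 50 ms Gaussian
  smoothing), per-neuron/per-timepoint regression with coefficients of
  partial determination, circular-shift permutation nulls with
  Benjamini–Hochberg correction, cross-validated representation projections,
  trial-type PCA trajectories, and 10-location population decoding.
- **`twostep.synth`** — generators for behavioural, optogenetic and neural
  cohorts with the statistical structure the analyses assume (population
  parameter distributions, planted stimulation effects, sparse event-like
  activity with planted tuning).
- **`twostep.io` / `twostep.cli` / `twostep.pipeline`** — tab-separated
  session formats, YAML configs, and a `twostep` command-line interface.

## Worked example

```python
import numpy as np
from twostep.synth import CohortSpec, generate_behavior_cohort
from twostep.behavior import build_design, fit_choice_regression

spec = CohortSpec(n_subjects=6, sessions_per_subject=2, trials_per_session=300)
sessions = generate_behavior_cohort(spec, np.random.default_rng(0))
design = build_design(sessions, kind="one_trial_back")
result = fit_choice_regression(design, n_boot=500, seed=0)
print(result.to_frame())
```

prints (loadings of the hierarchical logistic regression predicting each
choice from the previous trial's events):

```
         predictor   loading    ci_low   ci_high      p
0  bias_top_bottom  0.211899  0.011249  0.433164  0.044
1  bias_rotational  0.083170 -0.153354  0.232651  0.380
2           choice  2.625905  2.384628  2.878987  0.004
3          correct  1.308375  1.287491  1.332364  0.004
4          outcome  0.935155  0.824987  1.043291  0.004
5       transition  0.551110  0.193564  0.848632  0.008
6      trans_x_out  0.359081  0.037877  0.606284  0.020
```

The cohort is simulated from the full mixture model, so both rewards
(`outcome` > 0: rewarded choices are repeated) and common transitions
(`transition` > 0: the signature of model-based control with transition
learning) are reinforcing, while the transition-outcome interaction is
comparatively small — the qualitative pattern the task is designed to read
out.  `p` values are two-sided subject bootstraps; `ci` are 95% bootstrap
intervals on the population mean.

The same pipeline from the shell:

```sh
twostep simulate-agent --model best --n-sessions 10 --n-trials 300 --seed 0 --out cohort.tsv
twostep analyze-behavior --analysis onetrial --sessions cohort.tsv
twostep compare --models mf,mb,best --sessions cohort.tsv --k 500
```

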