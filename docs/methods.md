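# Methods

This note documents the models implemented by `twostep`, the choices made
where the design was genuinely open, the synthetic data the test suite runs
on, and the limitations of both.

## Task environments

**Two-step task.**  Trials consist of a first-step choice (top/bottom),
a probabilistic transition to a left- or right-active second-step state, and
a probabilistic reward.  A block is a pair (transition state, reward state):
transition state A maps top→left and bottom→right as the common (P = 0.8)
transition, state B the reverse; reward states are left-good, neutral and
right-good with good/neutral/bad reward probabilities 0.8/0.4/0.2.

Block transitions are behaviour-triggered.  In non-neutral blocks an
exponential moving average of the correct-choice indicator,
`ema ← ema + (I_correct − ema)/τ` with τ = 8, initialised at 0.5 at block
start, must exceed 0.75; the transition fires exactly 20 trials after the
first crossing.  The recurrence itself is our choice (the time constant is a
standard specification, the update form is not); this first-order form is
the natural discrete-time τ-trial average and makes the 75% threshold
meaningful.  In neutral blocks there is no correct choice: the EMA is not
updated, threshold logic is disabled, and the block ends with per-trial
hazard 0.1 after trial 40 (mean length 40 + 1/0.1 = 50 trials).  Triggered
transitions from non-neutral blocks go with probability 0.25 each to: the
reward reversal, the transition reversal, or one of the two neutral blocks;
neutral blocks exit to one of the two non-neutral reward states (0.5 each)
with the transition state unchanged.  Counters and the EMA reset at every
transition (the reset behaviour at transitions is unspecified upstream; a
fresh 0.5 start is the only choice that treats all blocks alike).

With `fixed_transitions` the transition state never changes and its 25%
transition-reversal mass is folded into the reward reversal — the minimal
redistribution consistent with "no transition reversals".

**Reversal-learning variant.**  Left/right choice, reward at the chosen
port (0.75/0.5/0.25 by block), threshold delay 10 trials, neutral hazard 0.1
after trial 15 (mean neutral length 25).  Block-exit structure mirrors the
fixed-transition two-step case (0.5 reward reversal / 0.5 neutral from
non-neutral blocks), since the variant has no transition state.

**Stimulation schedule.**  After each stimulated trial, 2 forced
non-stimulated trials, then stimulation with probability 0.25 per trial.
Expected inter-stimulation gap = 2 + 1/0.25 = 6 trials, hence a 1/6 (≈17%)
long-run stimulated fraction.

## The RL model family

Fourteen parameters: learning/forgetting rates α_Q, f_Q, λ, α_T, f_T, α_c,
α_m in (0, 1); non-negative value weights G_mf, G_mo, G_mb; unbounded biases
B_c (top/bottom), B_r (rotational) and perseveration strengths P_c, P_m.
Updates per trial (c = choice, s = second step reached, r ∈ {0, 1}):

- Q_mf(c) ← (1−α_Q)Q_mf(c) + α_Q(λr + (1−λ)V(s)); V(s) ← (1−α_Q)V(s) + α_Q r;
  the not-chosen action and not-visited state decay by (1−f_Q).  V(s) is
  read *before* its own update when forming the eligibility target.
- Transition estimates: P(s|c) ← (1−α_T)P(s|c) + α_T and its complement
  scaled by (1−α_T), so P(left|c) + P(right|c) = 1 identically; the
  not-chosen action's estimates decay toward 0.5 by f_T.
- Motor-level values Q_mo(c, s_prev) update like Q_mf on the visited entry;
  all other entries decay by (1−f_Q).
- Choice history c̄ ← (1−α_c)c̄ + α_c(c − 0.5); motor history m̄(s_prev)
  likewise, visited entry only.

Net values: Q_net(c) = G_mf Q_mf + G_mo Q_mo(c, s_prev) + G_mb Σ_s P(s|c)V(s)
+ X(c), with X applied to the top action only:
X(top) = B_c + B_r(s_prev − 0.5) + P_c c̄ + P_m m̄(s_prev), s_prev coded 1 for
left.  Choice probabilities are a plain softmax (no separate inverse
temperature: the G weights absorb value scaling).

Open choices made here: values, state values and transition estimates
initialise at 0.5 (the reward-scale midpoint and the fixed point of the
forgetting rules), histories at 0; on a session's first trial there is no
previous second-step state, so the motor-value, rotational-bias and
motor-perseveration terms are simply omitted rather than inventing a dummy
state; m̄ entries for unvisited previous states are not decayed;
perseveration histories reset at session start.

Component models are masks of the same engine: `mf` (α_Q, f_Q, λ, α_c, G_mf,
B_c, P_c — model-free with eligibility traces, value forgetting and
multi-trial perseveration), `mb` (α_Q, f_Q, α_T, f_T, α_c, G_mb, B_c, P_c —
model-based with value and transition forgetting), `best` (all 14).  Masked
rates are fixed at inert mid-range values; they only drive variables whose
weight is fixed at zero.

## Hierarchical fitting and model comparison

Per-unit parameter vectors live in a transformed space (logit for rates,
log for weights, identity for biases) where the population is Gaussian with
diagonal covariance.  EM alternates: (E) per-unit MAP fits under the current
prior with a Laplace covariance from the numerical Hessian
(central differences, step 1e-4; eigenvalues floored at 1e-6 before
inversion so the covariance is PSD); (M) moment updates
μ = mean(m_i), Σ = mean(m_i² + V_i) − μ² with a 1e-6 variance floor.
RL likelihood gradients are central differences over a numba forward-pass
kernel; the logistic likelihood uses damped Newton steps with its exact
Hessian.  MAP fits are warm-started from the previous iteration's modes;
multi-start jitter applies on the first iteration only.  Convergence is the
sup-norm change of μ (default tol 1e-4, max 100 iterations; the heavy
acceptance runs use tol ~1e-3 and 10–25 iterations, which the EM trajectory
plots show is past the point where μ has stabilised).  The default prior
initialisation is μ = 0, σ = 1–2 in transformed units.

The fitting unit is configurable (session or subject); the default is
session, matching how the synthetic generator draws parameters.

iBIC: −2·Σ_i log(1/K Σ_j p(D_i|h_j)) + |M| log|D|, with h_j sampled from the
fitted prior, |D| the total number of choices, and |M| counted as **two
prior parameters (mean and variance) per model parameter** — the literal
reading of "fitted parameters of the prior"; the constant is isolated in
`IBICResult.n_prior_params`.  Bootstrap CIs resample the K prior draws with
replacement within each unit.  K defaults to 5000 for reports; the test
suite uses K = 500 (scaled down).

**Known limitation (measured, not hypothetical).**  MAP-EM with a Laplace
E-step has an O(1) population-mean bias for weakly identified parameters:
the session-level posterior is skewed, its mode is not its mean, and the EM
feedback loop amplifies the per-session mode bias by ≈1/(1−ρ) where ρ is the
shrinkage weight.  At 500-trial sessions the full 14-parameter model leaves
λ, α_c and P_c weakly identified (session-level SE of several logit units),
and the recovered population means for those parameters sit ~0.2–0.3
transformed units from the truth regardless of how many sessions are fitted.
Diagnostics in the test suite and development notes verified that the
likelihood kernel matches a literal re-implementation to 1e-10, that
single-session maximum likelihood on long sessions is unbiased, and that the
average MAP mode at the *true* prior is unbiased — the displacement is a
property of the EM fixed point itself.  Consequence: the parameter-recovery
acceptance test can fail for the weakly identified parameters while the
well-identified ones (the G weights, biases, α_T, f_T) recover cleanly.
Model comparison by iBIC is unaffected (it compares data likelihoods, not
parameter values) and selects the generating model reliably.

## Behavioural statistics

Choice regressions predict the current choice (top = 1) with ±0.5-coded
predictors whose sign is carried by the referenced choice, which is
algebraically identical to predicting "repeat" and keeps trial-1 semantics.
The one-trial-back design uses bias, rotational bias, choice, correct,
outcome, transition and transition×outcome; the lagged design uses choice /
outcome / transition / interaction summed over lag bins 1, 2, 3–4, 5–8 and
9–12 (the upstream bin list "5-8, 8-12" double-counts lag 8 and conflicts
with the non-overlap requirement; 9–12 is the minimal repair) plus the two
biases; the reversal-task design uses bias plus choice and outcome at lags
1–3.  The interaction is +0.5 for common-and-rewarded or
rare-and-unrewarded, −0.5 otherwise; the correct predictor is 0 when the
previous trial was in a neutral block, and the rotational bias is 0 on a
session's first trial.  Responses within 20 trials of a
transition-probability reversal are excluded (common/rare is ambiguous
there); excluded trials still serve as lag-history sources by default, since
removing them there too roughly doubles the discarded data (switchable).

Permutation tests for stimulation effects refit the hierarchical model to
stimulated and non-stimulated trials, compare Δμ with an ensemble of
within-session label shuffles, and report P = 2·min(M/N, 1−M/N) — floored at
2/N, the smallest attainable value, so p ∈ (0, 1] — Bonferroni-corrected
over the three reported predictors (outcome, transition, interaction).
Group×stimulation interactions permute whole subjects between groups.
Bootstrap CIs and tests on population means resample per-subject mean MAP
loadings with replacement (5000 resamples by default) rather than re-running
EM per resample; the resampled statistic is exactly the cross-subject mean
the CI describes, and a full refit per resample is not tractable at desk
scale.

Reversal curves average P(post-reversal correct choice) by trials since
reversal and fit p(t) = p_end − (p_end − p_0)e^(−t/τ) by least squares, with
p_0 taken from the 5 pre-reversal trials; the fit is flagged uninformative
when the trajectory never rises above baseline by more than 3× the binomial
noise of its sparsest point.

A caveat the test suite documents explicitly: in block-structured tasks,
cross-trial correlations leave a small residual transition/interaction
loading (~4% of the outcome loading) even for purely model-free agents, with
the correct predictor included.  "Little loading" for the model-free agent
is therefore asserted relative to the outcome loading, not as exact
statistical zero at arbitrary power.

## Neural analyses

Activity is non-negative deconvolved events at 10 Hz.  Alignment linearly
rescales each trial's choice→outcome interval to the session median
(piecewise-linear, single segment; no dynamic time warping), samples a 20 Hz
grid from 1,000 ms pre-choice to 1,000 ms post-outcome by linear
interpolation, smooths with a 50 ms SD Gaussian, and optionally applies
log2(x + 1) — the offset (1.0, in `LOG2_OFFSET`) handles the zeros of
deconvolved activity and is recorded in the tensor's transform tag.

CPD regression fits ordinary least squares per neuron-timepoint;
CPD(p) = (SSE_reduced(p) − SSE_full)/SSE_reduced(p), clipped to [0, 1], with
near-perfectly-fit columns reported as 0 rather than 0/0 noise.  Population
CPD is the unweighted mean over neurons; sessions pool by concatenating
neurons, never trials.  Block-state predictors are coded 0 for 20 trials
after the relevant block change and ±0.5 otherwise (reward state:
−0.5/0/+0.5).  Significance uses circular shifts of each session's
predictor matrix by a uniform random number of trials (preserving
autocorrelation on both sides), p = fraction of permuted ≥ true, BH-corrected
across timepoints within each predictor.  Representation projections use
unit vectors from regression weights at two reference timepoints (midway
choice→outcome, and 250 ms post-outcome), cross-validated odd/even and
averaged.  Trial-type PCA subtracts each neuron's cross-type mean from its
8 per-type mean time courses and takes the SVD of the
[neurons × types·timepoints] matrix.  Decoding uses 250 ms half-open
windows (pre-choice from −300 ms; post-choice centred mid-interval;
post-outcome from +100 ms), 10 visits per location per session, multinomial
logistic regression with L2 regularisation (C = 1.0, inverse-strength
convention), stratified 10-fold CV, averaged over 10 visit selections;
sessions without full coverage are dropped.

## Synthetic data

Behavioural cohorts draw per-session parameter vectors from a population
Gaussian in transformed space and run the agent in closed loop with the
task.  The default population (natural-space means α_Q = 0.5, f_Q = 0.15,
λ = 0.7, α_T = 0.5, f_T = 0.15, α_c = α_m = 0.25, G_mf = 2, G_mo = 1.5,
G_mb = 3, B_c = 0.1, B_r = 0.2, P_c = P_m = 1; transformed-space SD 0.4 for
rates/weights, 0.2 for biases) is a set of plausible mid-range picks that
exercise every component of the mixture — they are deliberately **not**
claims about fitted animal values, and they are defined once in
`twostep.synth`.  Sessions chain within subject (a session starts in the
block its predecessor ended in).

Optogenetic cohorts flag trials by the scheduling rule (stim on trial t =
light from the previous trial's outcome through this trial's choice).  The
planted effect scales the transition-probability learning rate α_T by
(1 − effect) for the update performed during the illuminated window, so the
stimulated choice is made without having consolidated the previous trial's
observed transition.  This is a test-harness device implementing the
*finding* to be detected — reduced influence of transition information on
stimulated choices — not a mechanistic claim.  A caveat the power test
encodes: in this model family the reward's effect on the next choice is
routed through the freshly updated transition estimate (the reward at state
s promotes the action now believed to reach s), so at the generator's α_T
the suppression loads most strongly on the stimulated-trial *outcome*
predictor, with a milder drop in the marginal transition loading and a rise
in the interaction; transition and reward routing are structurally
entangled in this architecture and no single-knob suppression separates
them cleanly.

Neural sessions place Poisson event counts at 10 Hz on a baseline rate plus
Gaussian tuning kernels (SD 200 ms) locked to choice/outcome times, with
tuned subpopulations for choice, pre- and post-outcome second-step state
(orthogonal populations by construction) and outcome gated by second-step
state (separate left-port and right-port outcome cells).  The untuned
baseline is set so the population-mean event rate matches the target
(default 0.12 Hz).  What this emulates: sparse, non-negative, event-like
activity with planted low-dimensional tuning at realistic rates.  What it
does not: calcium indicator dynamics, deconvolution artifacts, correlated
noise across neurons, slow drift, or behaviour-locked motion artifacts —
passing tests therefore validate the *analysis machinery*, not robustness
to those real-data nuisances.

## Problem sizes of the standing test suite

The acceptance tests run: 100,000 simulated neutral blocks per task variant;
1,000,000 scheduled trials; label-shuffled decoding over 20 repetitions on a
3-session, 120-neuron synthetic cohort; parameter recovery on 100 sessions ×
500 trials (EM: 25 iterations, tol 3e-4); model selection over 10 seeded
repetitions of 20 sessions × 500 trials at K = 500, rotating the generating
model through {mf, mb, best}; regression sign structure on 200 sessions ×
500 trials per agent; permutation calibration over 80 null optogenetic
datasets × 100 permutations (pooled over the three reported predictors) and
30 null neural datasets × 200 circular shifts; planted-effect power at 20
subjects × 800 trials with 200 permutations.  These sizes are the
package's chosen desk-scale study conditions; the corresponding full-scale
defaults (n_perm = n_boot = 5000, K = 5000) remain the library defaults.
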