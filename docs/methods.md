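# Methods

`arbrl` implements an uncertainty-based arbitration model of goal-directed
(model-based, MB) versus habitual (model-free, MF) control on a two-step
Markov decision task, together with the machinery needed to study it without
access to human data: a task simulator, maximum-likelihood fitting, model and
parameter recovery, synthetic clinical-profile cohorts, and export of model
latents as fMRI parametric modulators.

## Task model

The task is a depth-two binary decision tree: a start state, two second-stage
states, and four terminal states, each holding a coin (colour in {red,
yellow, blue}, face value in {40, 20, 10, 0} points; default layout
`(red, 40), (blue, 20), (yellow, 10), (red, 0)`, configurable). Every
decision state offers `left`/`right`; each (state, action) has two candidate
successors and reaches the action-congruent one with probability
`p_common` — 0.9 under low transition uncertainty, 0.5 under high. Reward
depends on the block's goal condition: under a *specific* goal a coin pays
only if its colour matches the trial's goal colour (resampled uniformly over
the three colours every trial); under the *universal* (white) goal every
coin pays its face value. The 2×2 crossing of goal specificity and
transition uncertainty yields four blocks; (specific, low) favours MB
control and (universal, high) favours MF control.

A default experiment is six sessions of eight 5-trial block slots (each
condition twice per session, order shuffled; 40 trials/session, 240
analysed trials), preceded by a 100-trial pretraining session (80
universal/high then 20 specific/high trials) that warms up the learners and
is excluded from all analyses. Decision timeouts (a random choice imposed on
the subject, with a point penalty) exist as an optional mechanism and are
disabled by default; timeout trials are excluded from likelihoods. Stage
onsets are deterministic metadata (2 s ITI, 2.5 s between stages, 2 s reward
stage, choices 0.5 s after stage onset) used only by the regressor export.

## Learners

**MB learner.** A transition model `T(s, a, s')` starts uniform (0.5, 0.5)
and is updated from the state-prediction error `SPE = 1 - T(s, a, s_obs)`:
the observed entry moves by `eta_MB * SPE` and the row is renormalized.
Action values come from backward induction through the tree,
`Q_MB(s, a) = sum_s' T(s, a, s') [R(s') + max_a' Q_MB(s', a')]`, with
terminal rewards evaluated under the current trial's goal, so Q_MB re-plans
instantly when the goal colour changes. No discounting is applied — the
horizon is two steps.

**MF learner.** On-policy SARSA over the same states: the stage-1 backup
uses the actually chosen stage-2 action with zero intermediate reward
(`RPE_1 = Q_MF(s_2, a_2) - Q_MF(s_1, a_1)`), the terminal backup uses the
obtained points (`RPE_2 = r - Q_MF(s_2, a_2)`); both tables start at zero.

## Uncertainty estimators

**chi_MB** tracks SPE history with a decayed-count Dirichlet posterior over
K = 3 discretized SPE categories. Each update multiplies all pseudo-counts
(initialised at 1) by a forgetting factor `lam` and increments the observed
category; reliability is the posterior mean of the lowest-SPE category and
`chi_MB = 1 - reliability`. The effective sample size converges to
`1/(1 - lam)`.

Defaults: category edges `(0.45, 0.7)` and `lam = 0.7`. The low/medium
boundary sits just below the chance-level SPE of 0.5, so that transitions
predicted better than chance count as reliable evidence, and the ~1.7-trial
memory lets the estimator track the 5-trial block slots: with the wider
textbook-style bins (edge 0.3) and a long memory (`lam = 0.9`) the estimator
could not follow the fast block interleaving and P_MB was essentially flat
across conditions. Both settings are configurable.

**chi_MF** is Pearce–Hall associability: surprise `u = min(|RPE|/r_max, 1)`
with `r_max = 40` (the maximum coin value, making the signal scale-free),
integrated as `A <- A + eta_PH (u - A)`, starting at 0.5. Both RPEs of a
trial are assimilated. `max(chi_MB, chi_MF)` is computed per trial for the
replication-style regressor export.

## Arbitration

Control is allocated by a two-state transition model over {MB, MF}. The
rates are sigmoidal in the *other* strategy's unreliability:

    alpha = A_alpha / (1 + exp(B_alpha (1 - chi_MF)))      (MF -> MB)
    beta  = A_beta  / (1 + exp(B_beta  (1 - chi_MB)))      (MB -> MF)

and the probability of MB control follows
`dP_MB/dt = alpha (1 - P_MB) - beta P_MB`, integrated by forward Euler once
per trial after the reward stage (substep count configurable), clipped to
[0, 1], fixed point `alpha/(alpha+beta)`. P_MB starts at 0.5, is carried
across blocks, and resets at session boundaries (configurable). Both
decision stages of a trial use the same P_MB. Action values are mixed as
`Q_Arb = P_MB Q_MB + (1 - P_MB) Q_MF` and passed to a softmax with inverse
temperature `tau` on the points scale (so a fitted `tau` of 0.15 means a
20-point value gap yields ~95% choice consistency).

Within-trial order of operations (identical in the reference agent and the
compiled kernel): plan, stage-1 choice, first transition, SPE/posterior
update, stage-2 re-plan and choice, second transition, SPE/posterior
update, reward, both SARSA backups, both associability updates, rate
computation, one P_MB step.

Default rate-function settings (`A_alpha = 0.35`, `B_alpha = 1.5`,
`A_beta = 0.5`, `B_beta = 4`) were chosen, together with the chi_MB
settings above, so that the default agent operates in the regime the task is
designed to induce: mean P_MB above 0.5, higher in the MB-favoured than the
MF-favoured block, with block-to-block transitions fast enough to matter
within 5-trial slots. Because blocks interleave quickly relative to the
P_MB time constant (~5–10 trials), block means of P_MB are lag-attenuated;
the summary tables therefore attribute to each trial the post-update P_MB
(the arbitrator's state informed by that trial's evidence). The pre-choice
value is exported alongside it in every trial log.

## Likelihood, fitting, model comparison

The choice likelihood replays the agent deterministically through the
logged states, actions and outcomes, accumulating `-log P(s, a)` over both
decisions of every analysed trial (pretraining is replayed for warm-up but
not scored; timeout trials are excluded; per-choice probabilities are
floored at 1e-10). Simulation and replay share one compiled (numba) kernel,
so a replay at the generating parameters reproduces the forward
log-probabilities bit-for-bit; a pure-Python reference agent assembled from
the documented per-module operations is tested against the kernel at 1e-12.

Three variants are fitted per subject: the arbitration model and the
single-system reductions with P_MB pinned at 1 (MB-only) or 0 (MF-only).
Fitting is bounded multi-start L-BFGS-B (uniform seeded starts inside the
box, 20 restarts by default, all restart NLLs recorded, non-convergence
flagged). Bounds: learning rates and amplitudes (1e-3, 1), `tau` (1e-3, 1)
on the points scale.

Free parameters: arbitration {eta_MB, eta_MF, eta_PH, A_beta, tau};
single-system {own learning rate, tau}. The steepnesses B_alpha/B_beta and
the amplitude A_alpha are fixed by default (all overridable): chi_MF varies
little across task conditions, so alpha is nearly constant and the P_MB
path identifies the alpha/beta *ratio* but not the sum — freeing both
amplitudes left their recovery errors correlated at ~0.7 while A_beta
recovered at only r ≈ 0.34; pinning A_alpha transfers the identified ratio
onto A_beta (r ≈ 0.7–0.9 at 30 subjects × 240 trials).

AIC = 2k + 2 NLL and BIC = k ln(n) + 2 NLL with n the number of scored
choices (two per trial). Variants are compared per metric with Wilcoxon
signed-rank tests (exact null for n < 25). The per-block difference of
summed per-trial NLL between the MB-only and MF-only fits ("NLL ratio,
MB minus MF") is negative where goal-directed control explains choices
better. Parameter recovery simulates a cohort from known parameters, refits,
and reports Pearson correlations; degenerate generating distributions are
reported as missing correlations.

## Synthetic cohorts

Parameters are drawn from truncated normals on each parameter's bounded
scale. Two clinical-style profiles differ only where the modelling
literature on compulsivity localizes group differences: the OCD-like
profile has lower `tau` (0.08 ± 0.03 vs 0.15 ± 0.05 — less value-guided
choice) and higher `A_beta` (0.85 ± 0.08 vs 0.50 ± 0.10 — faster
MB-to-MF transfer) than the HC-like profile; learning rates and A_alpha are
shared. A broader `recovery` profile (means 0.4–0.5, sd 0.2–0.25; `tau`
0.2 ± 0.1) drives the recovery studies. Whether an elevated chi_MB arises
mechanistically or from these two parameters alone is left open; the
generator takes the minimal-manipulation stance.

What the generator emulates: block/session structure, goal resampling,
transition noise, point outcomes, and cohort-level parameter heterogeneity.
What it does not: reaction times, fatigue or attention drift, symptom
covariates, any within-subject nonstationarity of parameters. Passing
group-direction tests on these cohorts shows the pipeline can detect the
modelled differences at the stated sample sizes — not that real cohorts
would show them.

## Study sizes, determinism, numerical choices

The packaged studies use 20 subjects for model recovery, 30 for parameter
recovery, 12 for condition effects, and 30 per group for the group
contrast, each with ~240 analysed trials — the single-experiment scale of
the task design. All randomness flows from explicit integer seeds
(per-subject design and simulation seeds derived from a master seed by
fixed offsets); two runs with the same configuration are byte-identical,
which the run manifest verifies with SHA-256 hashes. Softmax uses
max-subtraction; transition-model rows are renormalized exactly by
complementation; P_MB is clipped to [0, 1] after each Euler step.

Known limitations and margins:

* Per-subject BIC model selection is conservative for the arbitration model
  (k = 5 vs 2 demands an NLL advantage of ~9.3 at 480 choices); HC-like
  cohorts clear the "lowest BIC" bar for roughly 45–80% of subjects
  depending on the cohort draw, while lowest-AIC rates are 90–100% and the
  paired signed-rank comparison favours the arbitration model decisively at
  every seed examined.
* Fitted A_beta and the fitted P_MB group contrast at n = 30/group are
  significant at most but not all cohort draws; fitted tau separates at
  every draw examined.
* eta_PH is essentially unidentifiable from choices alone (recovery r ≈ 0);
  it is kept free by default for comparability but should not be
  interpreted per subject.
* The chi_MB estimator is a decayed conjugate approximation chosen for
  testability; no claim is made that its per-trial values reproduce any
  particular hierarchical Bayesian formulation numerically.
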