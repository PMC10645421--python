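# Methods

`aarl` implements an end-to-end analysis pipeline for an approach-avoidance
reinforcement-learning task: a restless two-armed bandit in which one option
(the *conflict* option) probabilistically yields both reward and punishment
while the other (*safe*) option yields reward only. The package covers task
simulation, a family of Q-learning models, hierarchical empirical-Bayes
fitting, model comparison, behavioural statistics, mediation, reliability,
and a synthetic-cohort generator that makes every stage testable without
external data.

## Task environment

Latent outcome probabilities follow decaying Gaussian random walks

p(t+1) = λ·p(t) + (1 − λ)·θ + e,  e ~ N(0, σ²)

with defaults λ = 0.97, θ = 0.5, σ = 0.04 over 200 trials. Walks are
initialised at 0.7 (conflict reward), 0.5 (safe reward, before scaling) and
0.2 (conflict punishment); the whole safe-reward series is multiplied by
0.7, so it starts at 0.35 and averages below the conflict option. The
safe-punishment probability is identically zero.

Two choices the walk description leaves open:

* **Clipping.** Out-of-range values are clipped to [0.01, 0.99] each step.
  The decay centre at 0.5 makes excursions rare; keeping probabilities off
  0/1 keeps Bernoulli sampling and likelihoods non-degenerate.
* **Screening.** A candidate schedule is accepted only if all three pairwise
  Pearson correlations among the varying series are below 0.3 in absolute
  value (the zero series is excluded — its correlation is undefined).
  Rejection sampling is capped at 10,000 attempts. Because "mean correlation"
  is ambiguous between signed and absolute averaging, the diagnostics report
  both (`schedule_correlations`).

## Model family

Agents track four probability estimates (Q-values): reward and punishment
for each option. After each non-missed trial the chosen option's estimates
update by the Rescorla-Wagner rule Q ← Q + α(o − Q). Action weights combine
the estimates as W = β_r·Q_r − β_p·Q_p (or a single β multiplying the
difference), and choice follows a two-option softmax, optionally mixed with
a uniform lapse: P = (1 − ξ)·softmax(W) + ξ/2.

Six variants share or split the learning rates and sensitivities
(reward-only, punishment-only, symmetric, split rates, split sensitivities,
both split), each optionally with a lapse — twelve specifications in all.
Single-outcome variants zero out the irrelevant stream entirely, so they are
invariant to it.

Conventions the task description does not fix, chosen here and exposed as
configuration:

* **Softmax form.** The exponential softmax is used. A ratio form
  W(a)/ΣW(i) is not well defined once weights can be negative, which they
  are whenever the punishment term dominates.
* **Q initialisation.** All four estimates start at 0.5 (uninformative
  probability prior); configurable via `q_init`.
* **Missed trials** contribute nothing to the likelihood and trigger no
  update — no outcome is shown on a missed trial.
* **Lapse** is a uniform two-option mixture; ξ = 0 recovers pure softmax.

Parameters are estimated on an unbounded scale: rates and lapse map through
a sigmoid, sensitivities through an exponential. Likelihood and gradient
kernels are numba-compiled; the gradient is exact forward-mode
differentiation of the recursion (checked against finite differences to
1e-8 in the tests).

## Hierarchical fitting

`HierarchicalRLModel.fit()` runs expectation-maximisation with a Gaussian
population prior on the untransformed parameters:

* **E-step**: per-subject MAP estimation (multi-start L-BFGS-B with analytic
  gradients; 5 random restarts initially, warm starts plus the prior mean
  thereafter) and the Hessian of the negative log posterior at the optimum
  (central differences of the analytic gradient).
* **M-step**: population mean = mean of MAPs; population covariance = MAP
  scatter plus the mean inverse Hessian (the Laplace within-subject
  uncertainty, eigenvalue-floored at 1e-6), symmetrised with a 1e-6 ridge.
  The **full** covariance is retained — the joint two-session model needs
  cross-session covariances.

Convergence is declared when the maximum absolute change of the prior mean
falls below `tol` (default 1e-3; the large-cohort analyses use 2e-3).
The trace records a Laplace approximation of the marginal likelihood, which
is non-decreasing up to optimiser tolerance.

Model evidence uses the integrated BIC: minus twice the summed Monte-Carlo
log marginal likelihood of each subject under the fitted prior (default
2000 prior draws, seeded) plus a penalty of (number of prior
hyperparameters) × ln(total non-missed choices). Hyperparameters are
counted as d mean entries plus d(d+1)/2 free covariance entries, applied
identically to every model so comparisons are internally consistent.

## Behavioural statistics

* **Cleaning** applies three independent rules: more than one missed
  attention check; the same physical response key on ≥ 20 consecutive
  trials (the options switch screen sides randomly, so option-runs do not
  trigger it); ≥ 20 missed trials.
* **Choice regressions** are logistic mixed models of trial-by-trial choice
  on the reward-probability difference between options and the conflict
  option's punishment probability (optionally anxiety and its two
  interactions), with participant random intercepts via Laplace
  approximation (statsmodels `BinomialBayesMixedGLM.fit_map`); a
  fixed-effects fit with cluster-robust errors is the flagged fallback.
  Continuous predictors are z-scored by default (configurable) so
  coefficients are comparable across cohorts.
* **Kendall correlations** use tau-b with a permutation p-value:
  (count + 1)/(B + 1) per tail, two-sided by doubling the smaller tail,
  default B = 10,000.
* The **reward-punishment sensitivity index** is β_r/β_p (> 1 approach
  bias, < 1 avoidance bias); the learning-rate analogue is α_r/α_p.
* **Welch t-tests** come from scipy with Welch-Satterthwaite df and
  pooled-SD Cohen's d.

## Mediation

`parallel_mediation` estimates the parallel-mediator model by OLS path
regressions — for a just-identified model these coincide with the
saturated-path SEM estimates, so a full SEM engine is unnecessary. The
b-paths control for the exposure and the other mediators (mediators are
free to covary). Inference is a percentile bootstrap over participants
(default 2000 resamples) on standardised variables; missing rows are
dropped listwise and counted. The outcome in the anxiety analyses is the
proportion of conflict (approach) choices, so an anxiety-lowered
sensitivity index produces a *negative* indirect effect.

A calibration note: under a complete null the indirect effect a·b collapses
onto zero and any CI over-covers; the bootstrap behaves nominally under a
partial null (a ≠ 0, b = 0), which is what the calibration test uses.

## Reliability

Split halves cut a 200-trial session into trials 1–100 and 101–200 (odd
counts floor-split). Model-agnostic measures use Pearson correlations with
the Spearman-Brown correction 2r/(1 + r), or ICC(3,1) — two-way mixed,
consistency, single measures — for test-retest. Parameter reliability uses
the joint-model approach: both sessions of every participant enter one
hierarchical model whose per-subject vector stacks the two session blocks
under a full 2k×2k population covariance; each parameter's cross-session
covariance converts to a Pearson r. Fitting jointly avoids the attenuation
that correlating separately fitted point estimates suffers. Retest
simulations use fresh schedules per session, so reliability reflects
generalisation across environments rather than schedule memorisation.
Qualitative bands: < 0.40 poor, 0.40–0.60 fair, 0.60–0.75 good, > 0.75
excellent, applied to point estimates only.

## Synthetic cohorts

The generator draws per-subject parameters from a Gaussian population on
the untransformed scale, simulates each agent on accepted schedules (a pool
of four sets per cohort, as in multi-schedule study designs), emits
response keys under randomised side placement plus attention-check
outcomes, and can plant rule violators for cleaning tests.

Default population: α_r ≈ 0.45, α_p ≈ 0.25 (logit-scale SD 1.0),
β_r ≈ 5.5, β_p ≈ 1.7 (log-scale SD 0.7). The sensitivity balance was
calibrated so cohorts jointly approximate two properties typical of human
cohorts on this task: a mean
conflict-choice proportion near 0.5 — given schedules whose punishment
probability hovers near 0.4–0.5, equal sensitivities would make agents
strongly avoidant — and adequate parameter identifiability for
simulate-and-refit recovery. Females receive a small negative shift on the
reward-sensitivity latent (untransformed −0.2), a plausible small sex
difference in reward valuation.

Task-induced anxiety (0–50 slider, cohort mean 21, SD 14) is planted as a
linear function of the negated, standardised sensitivity-index latent and
punishment-learning-rate latent plus Gaussian noise, with target Kendall
correlations τ = −0.099 (index) and −0.088 (α_p). Because the latent is
Gaussian and tau is invariant to monotone transforms, the mixing weights
follow exactly from ρ = sin(πτ/2) — no calibration search. Rounding and
clipping of the slider attenuate the realised tau by at most ~0.01–0.02
(checked by simulation at n = 10,000). Retest cohorts draw session-2
parameters with a configurable per-parameter cross-session correlation and
fresh schedules.

What the generator does **not** emulate: response times, within-session
non-stationarity of preferences (fatigue, drift), questionnaire item-level
structure, volume/aversiveness heterogeneity of the punisher, or model
misspecification (agents are drawn from the fitted model class). Passing
tests therefore demonstrate that the pipeline is correct and well
calibrated under its own assumptions, not that those assumptions hold for
any particular human dataset.

## Known limitations and honest failures

* **Punishment learning rate is weakly identified** under these study
  conditions: punishments occur only on conflict choices (roughly half of
  trials at probability ~0.2–0.5), and a punishment sensitivity near 1.7
  gives the likelihood little curvature in α_p. Simulate-and-refit
  recovery for α_p settles around r ≈ 0.5–0.7 (the other three parameters
  reach 0.85–0.95), and the joint-model cross-session reliability of α_p
  plateaus well below a planted 0.7 even at full EM convergence. This is an
  information limit of the design, not an optimisation failure — and it is
  consistent with punishment-related parameters being the least reliable
  measures in this family of tasks.
* The EM covariance estimate can pick up moderate spurious inter-parameter
  correlations at small n; variational or MCMC fitting would quantify this
  better but is out of scope.
* iBIC depends on the hyperparameter-counting convention; only differences
  under the same convention are meaningful.
* Study sizes used by the test-suite and acceptance analyses (cohorts of
  60–500 agents, 100–200 trials, 5 replicate seeds) were chosen to exercise
  every stage at the scale of the original design while keeping a full run
  tractable on a single CPU.
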