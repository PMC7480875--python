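# Methods

## Task and environments

The unit of data is a session: 10 rounds of 20 selections among 64
options arranged on an 8×8 grid of two integer features (0–7 each),
interpreted as spatial location or as two stimulus features — the
geometry is identical and the task label is purely descriptive.
Environments are draws from a zero-mean Gaussian process over the grid
with RBF kernel `exp(-d²/2λ²)` (Euclidean `d` in raw grid units),
min-max normalized per draw so every surface spans exactly [0, 1].
Normalizing per draw (rather than jointly over a set) is an assumption;
it guarantees every round has the same latent minimum and maximum, which
is what the round-wise feedback scheme presumes. Sets of 40 environments
per class are generated with λ = 4 (smooth) and λ = 2 (rough); each
session draws its 10 rounds without replacement from one class set.

An observation of option *s* in a round with scale `S ~ U[80, 95]`
returns `means[s]·S + ε`, `ε ~ N(0, 1)`. The per-round scale is drawn so
the global maximum cannot be inferred from a single good reward. Round
10 is the bonus round: after 15 selections, 10 options unobserved so far
in that round are judged (expected reward 1–100, confidence 0–10),
followed by a forced choice among the judged options and 4 ordinary
trials.

## Learners

Rewards enter all learners as `(r − 50)/100`, mapping the mid-point of
the payoff scale to the GP's zero prior mean; predictions are mapped
back with the inverse transform. On this scale the generative
observation noise has variance 1e-4, and the GP's observation-noise
variance is fixed at that value rather than estimated — the free
parameters of the GP are λ, β, τ only. Kernel distances use raw grid
units, so fitted λ is commensurable with the generative λ ∈ {2, 4}.

The GP posterior is exact conditioning of the 64-dimensional prior on
the within-round history; beliefs reset at every round start (each round
has a fresh reward function, and the models are given that structural
knowledge). The Shepard variant replaces the Euclidean distance with a
Minkowski-ρ distance, ρ ∈ (0, 2]; at ρ = 2 it reproduces the RBF kernel
exactly. For ρ < 2 the kernel is not guaranteed positive definite; the
implementation therefore solves those systems by LU factorization and
clips negative posterior variances at zero, while the RBF path uses an
incremental Cholesky recursion (the two paths agree to < 1e-10 where
both apply, and the fast path is cross-checked against a stepwise
reference implementation in the tests).

The Bayesian mean tracker holds independent `N(m, v)` beliefs per
option, prior `m₀ = 0`, `v₀ = 5` on the normalized scale (a diffuse
prior an order of magnitude wider than the reward range; the original
analyses report only the error variance as a free parameter, so the
prior must be fixed by convention). Only the chosen option updates, by
Kalman gain `G = v/(v + θ²ₑ)`.

## Policy

Choice values are `q = m + β·v` with the posterior **variance**, as the
UCB rule is stated in this literature; a config switch (`ucb_uncertainty
= "sd"`) provides the standard-deviation variant, since which of the two
the original estimation used is not decidable from the printed rule.
Choice probabilities are a softmax of `q/τ` with max-subtraction; log
probabilities are computed in log space and are always finite, so log
loss is well defined even for near-deterministic parameter settings.

## Synthetic cohorts

Per-participant parameters are log-normal around configurable medians
with log-scale sd 0.5 (estimates in this paradigm are heavy-tailed and
span roughly half an order of magnitude around the median). GP cohorts
default to medians λ = 0.75 (undergeneralization relative to the
generative λ, as observed in fitted humans), β = 0.5, τ = 0.09. The
conceptual task multiplies each participant's β by 0.5 and τ by 2.0,
emulating the observed domain shift from directed to random exploration;
environment class and task order are balanced by alternation and both
tasks share a participant's class.

BMT cohorts use their own medians, θ²ₑ = 16.0, β = 0.01, τ = 0.03.
Three considerations fix these. First, the BMT bonus multiplies a prior
variance of 5, against 1 for the GP, so a bonus matched to the ±0.45
reward range must be roughly an order of magnitude smaller; with β near
the GP's 0.5 the bonus swamps all reward differences and simulated mean
trackers degenerate into reward-blind novelty searchers. Second, a
large error variance keeps the Kalman gain visibly below 1, i.e. the
mean tracker learns gradually — the regime in which it is a behaviorally
distinct hypothesis rather than a limit the GP can mimic with λ → 0
(the GP's observation noise is fixed and tiny, so it cannot imitate slow
updating). Third, a low temperature makes choices informative: these
agents are deliberate, slowly-updating exploiters whose revisit
patterns carry the model's signature. Model-recovery studies depend on
that signature; at a GP-like τ median of 0.09 the BMT's choices are too
stochastic for group-level selection to separate the models reliably.

Model-based **learning curves** are not simulated from generative BMT
cohorts but follow the estimate-sampling procedure
(`pipeline.simulate_learning_curves`): both models are first fitted to
the same generalizing cohort by cross-validation, and each replication
then samples one participant's fitted parameter set and plays the full
task. A mean tracker fitted to generalizing behavior is a poor learner
— its simulated curves sit just above the random baseline while the
fitted GP reproduces agent-like performance, giving the
GP > BMT > random ordering (and smooth > rough for the GP) as a result
of the procedure rather than a parameter choice.

A caveat the package surfaces honestly: under the GP cohort defaults
(β = 0.5 on the variance-form UCB), simulated GP agents do **not**
search below the 5.25 chance step distance — the uncertainty bonus for
never-visited options exceeds the maximum attainable posterior mean, so
step distances sit slightly above chance even while rewards and the
negative reward-distance correlation are human-like. Sub-chance local
search emerges for more exploitative settings (e.g. β ≤ 0.2, small τ),
which is what the locality analyses and examples use. Relatedly, the
conceptual-task adjustment (halving β, doubling τ) slightly *decreases*
simulated step distance rather than increasing it. Synthetic cohorts
reproduce the paradigm's learning, generalization and identifiability
phenomena, but not every distance-based signature of human search at the
default population medians.

Bonus-round judgments are generated from the agent's own posterior:
estimates are the denormalized posterior means, rounded and clipped to
[1, 100]; confidence is affine in the rank of the posterior variance
among the 10 judged options (least uncertain → 10), so with zero
judgment noise confidence is a strictly decreasing function of variance.
Judgment noise (default 0) is additive on the estimate scale with a
scaled-down analogue on the confidence scale. The random start stimulus
of every trial is recorded but does not enter any model: the learners
value all 64 options irrespective of cursor position, and trajectory
cost modelling is out of scope.

## Fitting

The round likelihood multiplies softmax probabilities of each observed
choice given the round's previous observations only. Maximum-likelihood
estimation uses differential evolution over `ln` parameters with bounds
`ln θ ∈ [−5, 4]` for λ, β, τ, θ²ₑ (ρ bounded [0.1, 2] untransformed);
bounds and optimizer settings (default popsize 20, 100 generations,
tol 1e-6, no polish, seeded) are package choices, exposed in
`OptimizerConfig`. The DE objective evaluates the entire candidate
population in one vectorized likelihood call per generation.

Cross-validation is leave-one-round-out over rounds 1–9 (the bonus round
is excluded everywhere except the bonus-round analyses); the
per-participant point estimate is the per-fold median, robust to
occasional bound-hitting folds. Predictive accuracy is
`1 − logL(M)/logL(random)` with `logL(random) = n·ln(1/64)` exactly.
Recovery studies in the tests and acceptance script use reduced DE
budgets (GP: popsize 10–15, 30–40 generations; BMT: popsize 15, 50
generations — the BMT likelihood is ~20× cheaper and under-optimized
BMT fits occasionally land on overconfident small-τ optima with
catastrophic held-out loss). Problem sizes throughout (40 agents for
parameter recovery, 20 per model for model recovery, ~500 simulated
rounds per learning-curve condition) are the package's standard
scaled-down study sizes.

## Model selection

Per-subject log model evidence is the negated cross-validated
out-of-sample log loss. Variational Bayes on the random-effects model
(models as colored marbles in a population urn, Dirichlet prior α₀ = 1)
alternates subject responsibilities and Dirichlet counts to convergence.
Exceedance probabilities are Monte-Carlo estimates from 10⁶ seeded
Dirichlet draws (the K = 2 case is validated against the closed-form
beta tail probability). The Bayesian omnibus risk compares the
variational free energy against the null in which every subject's model
is drawn uniformly (per-subject evidence averaged over models);
`pxp = xp·(1 − BOR) + BOR/K`. The free-energy bookkeeping follows the
standard variational random-effects formulation; any convention
satisfying the symmetric and dominant-model limits would do, and those
limits are what the tests pin down.

## Numerical and degenerate cases

- Environment sampling adds 1e-8 jitter to the prior covariance for
  Cholesky stability.
- The incremental Cholesky recursion floors pivot squares at 1e-12;
  with observation noise 1e-4 and ≤ 20 within-round observations the
  floor is never active for the RBF kernel.
- Softmax probabilities can underflow to exact zero for extreme `q/τ`;
  all likelihood code works in log space.
- Correlations over constant vectors (e.g. BMT bonus-round predictions)
  are reported as NaN, never coerced.
- A constant environment surface yields NaN correlogram entries.

## Limitations

- Synthetic cohorts emulate the statistical structure of the paradigm's
  data (design, parameter heterogeneity, domain shifts in β/τ), not
  human phenomena outside the models: no training-phase effects, no
  task-order transfer, no reaction times, no attention asymmetries.
  Passing recovery tests shows the pipeline identifies its own models
  under realistic conditions; it cannot certify conclusions about human
  data.
- The GP observation noise and BMT prior are fixed conventions; fitted
  parameters are interpretable only relative to them.
- Differential evolution with small budgets is a point-estimate
  procedure; no uncertainty on parameters is reported.
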