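"""Synthetic agents and cohorts with the full task structure.

Agents play the two-task design end to end: 10 rounds of 20 trials on
environments drawn without replacement from a 40-environment class set,
a uniformly random start stimulus each trial (recorded, but the models
value all 64 options regardless of cursor position), noisy rewards scaled
to a per-round maximum in [80, 95], and a bonus round that elicits reward
and confidence judgments for 10 unobserved options after trial 15.

Cohorts draw per-participant parameters from log-normal population
distributions and emulate the observed domain effect by shrinking the
exploration bonus and inflating the softmax temperature in the conceptual
task. Generating parameters are stored with each synthetic participant so
recovery studies are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import learners
from .data import (
    BONUS_JUDGMENT_TRIAL,
    N_JUDGMENTS,
    N_ROUNDS,
    N_TRIALS,
    ChoiceDataset,
    JudgmentSet,
    RoundData,
)
from .environments import Environment, RoundSpec, draw_scale_max, observe_reward
from .grid import N_OPTIONS
from .learners import (
    BeliefState,
    BMTConfig,
    KernelSpec,
    bmt_prior,
    bmt_update,
    gp_posterior,
    normalize_reward,
)
from .policy import ParamSet, choice_probabilities, sample_choice, ucb_values


@dataclass(frozen=True)
class DesignConfig:
    """Task design constants; defaults reproduce the study design."""

    n_rounds: int = N_ROUNDS
    n_trials: int = N_TRIALS
    bonus_round: bool = True
    judgment_trial: int = BONUS_JUDGMENT_TRIAL
    n_judgments: int = N_JUDGMENTS
    judgment_noise_sd: float = 0.0  # sd of noise added to judged estimates (0-100 scale)
    ucb_uncertainty: str = "variance"


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions for synthetic cohorts.

    Parameters are log-normal with the given medians and a common
    log-scale sd. The conceptual task multiplies each participant's beta
    by ``conceptual_beta_factor`` (< 1, less directed exploration) and tau
    by ``conceptual_tau_factor`` (> 1, more random exploration).

    Mean-tracker cohorts use their own beta and tau medians: the UCB
    bonus multiplies the posterior variance, whose prior scale is 5 for
    the BMT against 1 for the GP, so a bonus matched to the reward range
    must be an order of magnitude smaller; and mean-tracker agents are
    parameterized as deliberate, slowly-updating exploiters (large error
    variance, low temperature) so that their behavior carries the model's
    signature — gradual Kalman-gain learning without generalization —
    rather than dissolving into noise.
    """

    model: str = "gp"
    median_lambda: float = 0.75
    median_beta: float = 0.5
    median_tau: float = 0.09
    median_theta_eps2: float = 16.0
    median_beta_bmt: float = 0.01
    median_tau_bmt: float = 0.03
    median_rho: float = 2.0
    log_sd: float = 0.5
    conceptual_beta_factor: float = 0.5
    conceptual_tau_factor: float = 2.0
    design: DesignConfig = field(default_factory=DesignConfig)


class _Learner:
    """Incremental within-round belief tracker for one ParamSet."""

    def __init__(self, params: ParamSet):
        self.params = params
        if params.model in ("gp", "gp_shepard"):
            kind = "rbf" if params.model == "gp" else "shepard"
            self.spec = KernelSpec(kind=kind, lambda_=params.lambda_,
                                   rho=params.rho if params.rho is not None else 2.0)
        elif params.model == "bmt":
            self.cfg = BMTConfig(theta_eps2=params.theta_eps2)
        self.reset()

    def reset(self):
        if self.params.model in ("gp", "gp_shepard"):
            self.history = []
            self.belief = gp_posterior([], self.spec)
        elif self.params.model == "bmt":
            self.belief = bmt_prior(self.cfg)
        else:  # random: flat beliefs, history kept for bonus-round bookkeeping
            self.belief = BeliefState(np.zeros(N_OPTIONS), np.ones(N_OPTIONS), ())

    def observe(self, chosen: int, reward_raw: float):
        y = float(normalize_reward(reward_raw))
        if self.params.model in ("gp", "gp_shepard"):
            self.history.append((chosen, y))
            self.belief = gp_posterior(self.history, self.spec)
        elif self.params.model == "bmt":
            self.belief, _ = bmt_update(self.belief, self.cfg, chosen, y)
        else:
            self.belief = BeliefState(self.belief.post_mean, self.belief.post_var,
                                      self.belief.history + ((chosen, y),))

    def probabilities(self, design: DesignConfig) -> np.ndarray:
        if self.params.model == "random":
            return np.full(N_OPTIONS, 1.0 / N_OPTIONS)
        q = ucb_values(self.belief, self.params.beta, design.ucb_uncertainty)
        return choice_probabilities(q, self.params.tau)


def _participant_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: one generator per (seed, key...) tuple."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _confidence_from_variance(variances: np.ndarray, rng: np.random.Generator,
                              noise_sd: float) -> np.ndarray:
    """Map posterior variance onto the 0-10 confidence scale.

    Confidence is affine in the variance rank among the judged options —
    the least uncertain option earns 10, the most uncertain 0 — with
    optional discrete judgment noise. With 10 judged options and zero
    noise the rounded values are all distinct, so confidence is a strictly
    decreasing function of posterior variance.
    """
    order = np.argsort(np.argsort(variances, kind="stable"), kind="stable")
    denom = max(len(variances) - 1, 1)
    conf = np.round(10.0 * (1.0 - order / denom))
    if noise_sd > 0:
        conf = conf + rng.normal(0.0, noise_sd, size=len(conf))
    return np.clip(np.round(conf), 0, 10).astype(np.int64)


def _play_round(learner: _Learner, env: Environment, spec: RoundSpec,
                design: DesignConfig, rng: np.random.Generator):
    """Simulate one round; returns RoundData and (for bonus) a JudgmentSet."""
    learner.reset()
    starts, chosen, rewards = [], [], []
    judgments = None
    for t in range(design.n_trials):
        if spec.is_bonus and t == design.judgment_trial:
            judgments, forced = _elicit_judgments(learner, design, rng)
            j = forced
        else:
            p = learner.probabilities(design)
            j = sample_choice(p, rng)
        starts.append(int(rng.integers(N_OPTIONS)))
        chosen.append(j)
        r = observe_reward(env, spec, j, rng)
        rewards.append(r)
        learner.observe(j, r)
    return RoundData(spec=spec, start=np.array(starts), chosen=np.array(chosen),
                     reward=np.array(rewards)), judgments


def _elicit_judgments(learner: _Learner, design: DesignConfig, rng: np.random.Generator):
    """Judge 10 unselected options, then force a choice among them."""
    seen = {int(j) for j, _ in learner.belief.history}
    unseen = np.array(sorted(set(range(N_OPTIONS)) - seen), dtype=np.int64)
    if len(unseen) < design.n_judgments:
        raise ValueError("not enough unobserved options for judgments")
    judged = rng.choice(unseen, size=design.n_judgments, replace=False)

    mean = learner.belief.post_mean[judged]
    var = learner.belief.post_var[judged]
    est = learners.denormalize_reward(mean)
    if design.judgment_noise_sd > 0:
        est = est + rng.normal(0.0, design.judgment_noise_sd, size=len(est))
    est = np.clip(np.round(est), 1, 100).astype(np.int64)

    conf = _confidence_from_variance(var, rng, design.judgment_noise_sd / 10.0)

    if learner.params.model == "random":
        p = np.full(design.n_judgments, 1.0 / design.n_judgments)
    else:
        q = mean + learner.params.beta * (np.sqrt(var) if design.ucb_uncertainty == "sd" else var)
        p = choice_probabilities(q, learner.params.tau)
    forced = int(judged[sample_choice(p, rng)])
    return JudgmentSet(options=judged, estimate=est, confidence=conf,
                       forced_choice=forced), forced


def simulate_agent(params: ParamSet, env_set, design: DesignConfig | None = None,
                   seed: int = 0, participant_id: str = "agent-0", task: str = "spatial",
                   task_order: str = "first") -> ChoiceDataset:
    """Simulate one agent over the full task; deterministic given the seed.

    Environments for the 10 rounds are drawn without replacement from
    ``env_set``. Each trial the agent computes its posterior, values the
    options by UCB, samples a choice from the softmax, observes a noisy
    scaled reward, and updates its belief; beliefs reset at round start.
    """
    design = design or DesignConfig()
    if len(env_set) < design.n_rounds:
        raise ValueError("environment set smaller than the number of rounds")
    rng = _participant_rng(seed)
    order = rng.choice(len(env_set), size=design.n_rounds, replace=False)
    learner = _Learner(params)
    rounds, judgments = [], None
    for i, env_i in enumerate(order, start=1):
        env = env_set[env_i]
        spec = RoundSpec(env_id=env.env_id, round_index=i, scale_max=draw_scale_max(rng),
                         is_bonus=design.bonus_round and i == design.n_rounds)
        rnd, js = _play_round(learner, env, spec, design, rng)
        rounds.append(rnd)
        if js is not None:
            judgments = js
    return ChoiceDataset(
        participant_id=participant_id, task=task,
        env_class=env_set[order[0]].env_class, task_order=task_order,
        rounds=tuple(rounds), judgments=judgments, params=params,
    )


def simulate_bonus_round(params: ParamSet, env: Environment, seed: int = 0,
                         design: DesignConfig | None = None):
    """Simulate a single bonus round on one environment.

    Returns ``(trials 1-15, JudgmentSet, trials 16-20)`` where trial 16 is
    the forced choice among the judged options.
    """
    design = design or DesignConfig()
    rng = _participant_rng(seed)
    spec = RoundSpec(env_id=env.env_id, round_index=design.n_rounds,
                     scale_max=draw_scale_max(rng), is_bonus=True)
    learner = _Learner(params)
    rnd, judgments = _play_round(learner, env, spec, design, rng)
    k = design.judgment_trial
    pre = RoundData(spec=spec, start=rnd.start[:k], chosen=rnd.chosen[:k], reward=rnd.reward[:k])
    post = RoundData(spec=spec, start=rnd.start[k:], chosen=rnd.chosen[k:], reward=rnd.reward[k:])
    return pre, judgments, post


def random_baseline(design: DesignConfig | None = None, env_set=None, seed: int = 0,
                    participant_id: str = "random-0", task: str = "spatial") -> ChoiceDataset:
    """Uniform-choice agent; the chance baseline for reward and step distance."""
    return simulate_agent(ParamSet(model="random"), env_set, design, seed,
                          participant_id=participant_id, task=task)


def draw_population_params(cfg: CohortConfig, rng: np.random.Generator) -> ParamSet:
    """One draw of base (spatial-task) parameters from the population."""
    def ln(median):
        return float(median * np.exp(rng.normal(0.0, cfg.log_sd)))

    if cfg.model == "gp":
        return ParamSet(model="gp", lambda_=ln(cfg.median_lambda),
                        beta=ln(cfg.median_beta), tau=ln(cfg.median_tau))
    if cfg.model == "gp_shepard":
        rho = float(min(cfg.median_rho * np.exp(rng.normal(0.0, cfg.log_sd / 4)), 2.0))
        return ParamSet(model="gp_shepard", lambda_=ln(cfg.median_lambda), rho=rho,
                        beta=ln(cfg.median_beta), tau=ln(cfg.median_tau))
    if cfg.model == "bmt":
        return ParamSet(model="bmt", theta_eps2=ln(cfg.median_theta_eps2),
                        beta=ln(cfg.median_beta_bmt), tau=ln(cfg.median_tau_bmt))
    if cfg.model == "random":
        return ParamSet(model="random")
    raise ValueError(f"unknown model {cfg.model!r}")


def _for_task(base: ParamSet, cfg: CohortConfig, task: str) -> ParamSet:
    if base.model == "random" or task != "conceptual":
        return base
    return replace(base, beta=base.beta * cfg.conceptual_beta_factor,
                   tau=base.tau * cfg.conceptual_tau_factor)


def generate_cohort(n_participants: int, cfg: CohortConfig | None = None, seed: int = 0,
                    smooth_envs=None, rough_envs=None, tasks=("spatial", "conceptual")):
    """Generate a balanced synthetic cohort; two datasets per participant.

    Environment class and task order are balanced by alternation; each
    participant's parameters are one draw from the population
    distributions, with the conceptual-task beta/tau adjustment applied.
    Both tasks use the participant's assigned environment class.
    """
    from .environments import LAMBDA_ROUGH, LAMBDA_SMOOTH, generate_environment_set

    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    cfg = cfg or CohortConfig()
    if smooth_envs is None:
        smooth_envs = generate_environment_set(LAMBDA_SMOOTH, 40, seed=seed + 1)
    if rough_envs is None:
        rough_envs = generate_environment_set(LAMBDA_ROUGH, 40, seed=seed + 2)
    datasets = []
    for i in range(n_participants):
        env_class = "smooth" if i % 2 == 0 else "rough"
        envs = smooth_envs if env_class == "smooth" else rough_envs
        first_task = tasks[0] if (i // 2) % 2 == 0 else tasks[1]
        prng = _participant_rng(seed, i)
        base_params = draw_population_params(cfg, prng)
        for task in tasks:
            order = "first" if task == first_task else "second"
            ds = simulate_agent(
                _for_task(base_params, cfg, task), envs, cfg.design,
                seed=int(np.random.SeedSequence(seed, spawn_key=(i, tasks.index(task))).generate_state(1)[0] & 0x7FFFFFFF),
                participant_id=f"syn-{i:03d}", task=task, task_order=order,
            )
            datasets.append(ds)
    return datasets
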