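"""Cross-validated maximum-likelihood fitting of learner + policy models.

The likelihood of a round is the product of softmax choice probabilities,
where trial ``t``'s probability is computed from that round's first
``t - 1`` observations only (beliefs reset at round start). Parameters are
estimated by differential evolution over log-scaled parameters, and model
comparison uses leave-one-round-out cross-validation over rounds 1-9 (the
bonus round is excluded): fit on 8 rounds, score the held-out round by its
out-of-sample log loss. Predictive accuracy is summarized as a pseudo-R^2,
``1 - logL(M) / logL(random)``, which is 0 at chance and 1 for a perfect
predictor.

Two likelihood code paths exist on purpose: :func:`choice_log_likelihood`
recomputes the posterior stepwise through the reference learners, while
the fitting objective evaluates a whole differential-evolution population
at once with batched linear algebra. They agree to high precision and are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution
from scipy.special import logsumexp

from .data import ChoiceDataset, RoundData
from .grid import COORDS, N_OPTIONS, SQ_EUCLIDEAN
from .learners import (
    BMT_PRIOR_MEAN,
    BMT_PRIOR_VAR,
    GP_NOISE_VAR,
    BMTConfig,
    KernelSpec,
    bmt_prior,
    bmt_update,
    gp_posterior,
    normalize_reward,
)
from .policy import ParamSet, log_choice_probability, ucb_values

LOG_BOUNDS = (-5.0, 4.0)  # natural-log bounds for lambda, beta, tau, theta_eps2
RHO_BOUNDS = (0.1, 2.0)  # Minkowski exponent, untransformed

_LOG_UNIFORM = float(np.log(1.0 / N_OPTIONS))


@dataclass(frozen=True)
class OptimizerConfig:
    """Differential-evolution settings (seeded, deterministic)."""

    popsize: int = 20
    maxiter: int = 100
    tol: float = 1e-6
    polish: bool = False


@dataclass(frozen=True)
class FitResult:
    """Cross-validation outcome for one participant x model."""

    participant_id: str
    task: str
    model: str
    fold_params: tuple  # ParamSet per held-out round
    fold_loglik: tuple  # held-out log likelihood per fold
    total_loglik: float  # summed out-of-sample log likelihood
    pseudo_r2: float
    params: ParamSet  # per-fold median point estimate
    converged: bool


# ---------------------------------------------------------------------------
# round stacking

def _stack_rounds(rounds: list[RoundData]):
    """(R, T) arrays of chosen flat indices and normalized rewards."""
    n_trials = {r.n_trials for r in rounds}
    if len(n_trials) != 1:
        raise ValueError("all rounds must have the same number of trials")
    chosen = np.stack([r.chosen for r in rounds])
    y = normalize_reward(np.stack([r.reward for r in rounds]))
    return chosen, y


# ---------------------------------------------------------------------------
# population-vectorized likelihoods

def _shepard_sq_dist(rho: np.ndarray) -> np.ndarray:
    """(S, 64, 64) squared Minkowski-rho distances, one matrix per candidate."""
    diff = np.abs(COORDS[:, None, :] - COORDS[None, :, :]).astype(float)  # (64,64,2)
    r = rho[:, None, None, None]
    d = np.sum(diff[None] ** r, axis=-1) ** (1.0 / rho[:, None, None])
    return d**2


def _gp_loglik_population(theta: np.ndarray, chosen: np.ndarray, y: np.ndarray,
                          kind: str = "rbf", noise_var: float = GP_NOISE_VAR,
                          ucb_uncertainty: str = "variance") -> np.ndarray:
    """Log likelihood of all rounds for S candidate (lambda[, rho], beta, tau)."""
    theta = np.atleast_2d(theta)
    S = theta.shape[0]
    R, T = chosen.shape
    if kind == "shepard":
        lam, rho, beta, tau = theta.T
        sq = _shepard_sq_dist(rho)
    else:
        lam, beta, tau = theta.T
        sq = SQ_EUCLIDEAN[None]
    K = np.exp(-sq / (2.0 * lam[:, None, None] ** 2))  # (S, 64, 64)
    if K.shape[0] == 1 and S > 1:
        K = np.broadcast_to(K, (S, N_OPTIONS, N_OPTIONS))
    if kind == "shepard":
        # Minkowski-rho kernels with rho < 2 need not be positive
        # definite, so the Cholesky recursion below does not apply.
        return _gp_loglik_solve(K, beta, tau, chosen, y, noise_var, ucb_uncertainty)

    # Incremental Cholesky of the observation Gram matrix, shared across
    # the candidate population: row t of `c` holds L^-1 K(obs, all 64) and
    # `a` holds L^-1 y, so the posterior is m = a^T c, v = 1 - sum(c^2).
    ll = np.full(S, R * _LOG_UNIFORM)  # trial 1: uniform prior, q constant
    r_idx = np.arange(R)
    c = np.zeros((S, R, T, N_OPTIONS))
    a = np.zeros((S, R, T))
    m = np.zeros((S, R, N_OPTIONS))
    v = np.ones((S, R, N_OPTIONS))
    beta_ = beta[:, None, None]
    tau_ = tau[:, None, None]
    for t in range(1, T):
        j = chosen[:, t - 1]  # option observed on the previous trial, per round
        krow = K[:, j, :]  # (S, R, 64)
        if t == 1:
            l_dot_c = np.zeros((S, R, N_OPTIONS))
            l_dot_a = np.zeros((S, R))
            lsq = np.zeros((S, R))
        else:
            cc = c[:, :, : t - 1, :]
            l = np.take_along_axis(cc, j[None, :, None, None], axis=3)[..., 0]  # (S,R,t-1)
            l_dot_c = np.einsum("srt,srto->sro", l, cc)
            l_dot_a = np.einsum("srt,srt->sr", l, a[:, :, : t - 1])
            lsq = np.einsum("srt,srt->sr", l, l)
        d = np.sqrt(np.clip(1.0 + noise_var - lsq, 1e-12, None))
        crow = (krow - l_dot_c) / d[:, :, None]
        arow = (y[None, :, t - 1] - l_dot_a) / d
        c[:, :, t - 1, :] = crow
        a[:, :, t - 1] = arow
        m += arow[:, :, None] * crow
        v = np.maximum(v - crow**2, 0.0)

        u = np.sqrt(v) if ucb_uncertainty == "sd" else v
        z = (m + beta_ * u) / tau_
        ll += (z[:, r_idx, chosen[:, t]] - logsumexp(z, axis=-1)).sum(axis=1)
    return ll


def _gp_loglik_solve(K, beta, tau, chosen, y, noise_var, ucb_uncertainty):
    """Direct-solve GP likelihood (LU per prefix); no PD assumption on K."""
    S = K.shape[0]
    R, T = chosen.shape
    ll = np.full(S, R * _LOG_UNIFORM)
    r_idx = np.arange(R)
    eye = np.eye(T, dtype=float)
    for t in range(1, T):
        idx = chosen[:, :t]  # (R, t)
        gram = K[:, idx[:, :, None], idx[:, None, :]] + noise_var * eye[:t, :t]
        kstar = K[:, :, idx].transpose(0, 2, 1, 3)  # (S, R, 64, t)
        rhs = np.concatenate(
            [np.broadcast_to(y[None, :, :t, None], (S, R, t, 1)),
             kstar.transpose(0, 1, 3, 2)], axis=-1)
        sol = np.linalg.solve(gram, rhs)
        m = np.einsum("srot,srt->sro", kstar, sol[..., 0])
        v = np.maximum(1.0 - np.einsum("srot,srto->sro", kstar, sol[..., 1:]), 0.0)
        u = np.sqrt(v) if ucb_uncertainty == "sd" else v
        z = (m + beta[:, None, None] * u) / tau[:, None, None]
        ll += (z[:, r_idx, chosen[:, t]] - logsumexp(z, axis=-1)).sum(axis=1)
    return ll


def _bmt_loglik_population(theta: np.ndarray, chosen: np.ndarray, y: np.ndarray,
                           m0: float = BMT_PRIOR_MEAN, v0: float = BMT_PRIOR_VAR,
                           ucb_uncertainty: str = "variance") -> np.ndarray:
    """Log likelihood for S candidate (theta_eps2, beta, tau) triples."""
    theta = np.atleast_2d(theta)
    S = theta.shape[0]
    R, T = chosen.shape
    eps2, beta, tau = theta.T
    m = np.full((S, R, N_OPTIONS), m0)
    v = np.full((S, R, N_OPTIONS), v0)
    ll = np.zeros(S)
    r_idx = np.arange(R)
    for t in range(T):
        u = np.sqrt(v) if ucb_uncertainty == "sd" else v
        z = (m + beta[:, None, None] * u) / tau[:, None, None]
        ll += (z[:, r_idx, chosen[:, t]] - logsumexp(z, axis=-1)).sum(axis=1)
        j = chosen[:, t]
        vj = v[:, r_idx, j]
        gain = vj / (vj + eps2[:, None])
        m[:, r_idx, j] += gain * (y[None, :, t] - m[:, r_idx, j])
        v[:, r_idx, j] = (1.0 - gain) * vj
    return ll


def log_likelihood(params: ParamSet, rounds: list[RoundData],
                   ucb_uncertainty: str = "variance") -> float:
    """Summed choice log likelihood of the given rounds under one ParamSet."""
    chosen, y = _stack_rounds(rounds)
    if params.model == "random":
        return float(chosen.size * _LOG_UNIFORM)
    if params.model == "bmt":
        out = _bmt_loglik_population(
            np.array([[params.theta_eps2, params.beta, params.tau]]),
            chosen, y, ucb_uncertainty=ucb_uncertainty)
    elif params.model == "gp_shepard":
        out = _gp_loglik_population(
            np.array([[params.lambda_, params.rho, params.beta, params.tau]]),
            chosen, y, kind="shepard", ucb_uncertainty=ucb_uncertainty)
    else:
        out = _gp_loglik_population(
            np.array([[params.lambda_, params.beta, params.tau]]),
            chosen, y, ucb_uncertainty=ucb_uncertainty)
    return float(out[0])


# ---------------------------------------------------------------------------
# stepwise reference likelihood

def choice_log_likelihood(params: ParamSet, round_data: RoundData,
                          ucb_uncertainty: str = "variance") -> float:
    """Round log likelihood via stepwise posterior recomputation.

    Reference implementation built on the learner primitives; slower than
    the vectorized path used for optimization but independent of it.
    """
    if params.model == "random":
        return round_data.n_trials * _LOG_UNIFORM
    y = normalize_reward(round_data.reward)
    ll = 0.0
    if params.model == "bmt":
        state = bmt_prior(BMTConfig(theta_eps2=params.theta_eps2))
        for t in range(round_data.n_trials):
            q = ucb_values(state, params.beta, ucb_uncertainty)
            ll += log_choice_probability(q, params.tau, int(round_data.chosen[t]))
            state, _ = bmt_update(state, BMTConfig(theta_eps2=params.theta_eps2),
                                  int(round_data.chosen[t]), float(y[t]))
        return ll
    kind = "shepard" if params.model == "gp_shepard" else "rbf"
    spec = KernelSpec(kind=kind, lambda_=params.lambda_,
                      rho=params.rho if params.rho is not None else 2.0)
    history = []
    for t in range(round_data.n_trials):
        belief = gp_posterior(history, spec)
        q = ucb_values(belief, params.beta, ucb_uncertainty)
        ll += log_choice_probability(q, params.tau, int(round_data.chosen[t]))
        history.append((int(round_data.chosen[t]), float(y[t])))
    return ll


# ---------------------------------------------------------------------------
# maximum-likelihood estimation

def _model_bounds(model: str):
    if model == "gp_shepard":
        return [LOG_BOUNDS, RHO_BOUNDS, LOG_BOUNDS, LOG_BOUNDS]
    return [LOG_BOUNDS, LOG_BOUNDS, LOG_BOUNDS]


def _decode(model: str, x: np.ndarray) -> np.ndarray:
    """Map optimizer coordinates to natural-scale parameter rows."""
    x = np.atleast_2d(x)
    out = np.exp(x)
    if model == "gp_shepard":
        out[:, 1] = x[:, 1]  # rho is optimized untransformed
    return out


def _to_paramset(model: str, row: np.ndarray) -> ParamSet:
    if model == "gp":
        return ParamSet(model="gp", lambda_=row[0], beta=row[1], tau=row[2])
    if model == "gp_shepard":
        return ParamSet(model="gp_shepard", lambda_=row[0], rho=row[1],
                        beta=row[2], tau=row[3])
    if model == "bmt":
        return ParamSet(model="bmt", theta_eps2=row[0], beta=row[1], tau=row[2])
    raise ValueError(f"cannot fit model {model!r}")


def fit_mle(model: str, dataset: ChoiceDataset, train_rounds=None,
            opt: OptimizerConfig | None = None, seed: int = 0,
            ucb_uncertainty: str = "variance"):
    """Maximum-likelihood ParamSet on the training rounds.

    Differential evolution over log-scaled parameters within fixed bounds
    (``rho`` untransformed); the whole candidate population is scored in
    one vectorized likelihood call per generation. Deterministic given the
    seed. Returns ``(ParamSet, train log likelihood, converged flag)``.
    """
    if model == "random":
        rounds = train_rounds if train_rounds is not None else dataset.training_rounds()
        return ParamSet(model="random"), log_likelihood(ParamSet(model="random"), rounds), True
    opt = opt or OptimizerConfig()
    rounds = train_rounds if train_rounds is not None else dataset.training_rounds()
    if len(rounds) < 1:
        raise ValueError("need at least one training round")
    chosen, y = _stack_rounds(rounds)

    if model == "bmt":
        def loglik(theta):
            return _bmt_loglik_population(theta, chosen, y, ucb_uncertainty=ucb_uncertainty)
    else:
        kind = "shepard" if model == "gp_shepard" else "rbf"

        def loglik(theta):
            return _gp_loglik_population(theta, chosen, y, kind=kind,
                                         ucb_uncertainty=ucb_uncertainty)

    def objective(x):
        single = x.ndim == 1
        theta = _decode(model, x.T if not single else x)
        out = -loglik(theta)
        return out[0] if single else out

    result = differential_evolution(
        objective, bounds=_model_bounds(model), seed=seed, popsize=opt.popsize,
        maxiter=opt.maxiter, tol=opt.tol, polish=opt.polish,
        vectorized=True, updating="deferred",
    )
    row = _decode(model, result.x)[0]
    return _to_paramset(model, row), float(-result.fun), bool(result.success)


def crossvalidate(model: str, dataset: ChoiceDataset, opt: OptimizerConfig | None = None,
                  seed: int = 0, ucb_uncertainty: str = "variance") -> FitResult:
    """Leave-one-round-out cross-validation over the non-bonus rounds.

    Each of rounds 1-9 is held out exactly once; parameters fit on the
    other 8 rounds score it out of sample. The per-participant point
    estimate is the per-fold median of each parameter.
    """
    rounds = dataset.training_rounds()
    fold_params, fold_ll, converged = [], [], True
    for k in range(len(rounds)):
        train = [r for i, r in enumerate(rounds) if i != k]
        params, _, ok = fit_mle(model, dataset, train_rounds=train, opt=opt,
                                seed=seed + k, ucb_uncertainty=ucb_uncertainty)
        converged &= ok
        fold_params.append(params)
        fold_ll.append(log_likelihood(params, [rounds[k]], ucb_uncertainty))
    total_ll = float(sum(fold_ll))
    n_choices = sum(r.n_trials for r in rounds)
    pseudo_r2 = 1.0 - total_ll / (n_choices * _LOG_UNIFORM)
    if model == "random":
        median = ParamSet(model="random")
    else:
        rows = np.stack([p.free_values() for p in fold_params])
        median = _to_paramset(model, np.median(rows, axis=0))
    return FitResult(
        participant_id=dataset.participant_id, task=dataset.task, model=model,
        fold_params=tuple(fold_params), fold_loglik=tuple(fold_ll),
        total_loglik=total_ll, pseudo_r2=float(pseudo_r2), params=median,
        converged=converged,
    )


def fit_cohort(datasets, models, opt: OptimizerConfig | None = None, seed: int = 0):
    """Cross-validate every dataset under every model.

    Returns ``(results, evidence)`` where ``results[model]`` is the list
    of :class:`FitResult` in dataset order and ``evidence`` is the
    (n_datasets, n_models) matrix of out-of-sample log likelihoods used as
    log model evidence for group-level Bayesian model selection.
    """
    results = {m: [] for m in models}
    for i, ds in enumerate(datasets):
        for m in models:
            results[m].append(crossvalidate(m, ds, opt=opt, seed=seed + 1000 * i))
    evidence = np.array([[results[m][i].total_loglik for m in models]
                         for i in range(len(datasets))])
    return results, evidence
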