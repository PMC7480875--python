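"""Belief-updating models: GP regression and the Bayesian Mean Tracker.

Two learners map a within-round history of (option, reward) observations
to a posterior mean and variance over all 64 options:

* **GP regression** with an RBF kernel ``k(s, s') = exp(-d^2 / (2 lambda^2))``
  generalizes across options — observing one option informs beliefs about
  similar (nearby) options, with length-scale ``lambda`` setting the breadth
  of generalization. A Shepard variant replaces the Euclidean distance with
  a Minkowski-``rho`` distance (``rho = 2`` recovers the RBF exactly;
  ``rho < 2`` treats the two feature dimensions more separably).

* The **Bayesian Mean Tracker (BMT)** is a time-invariant Kalman filter
  holding independent normal beliefs per option; only the chosen option is
  updated, by a Kalman-gain-weighted prediction error. It learns but does
  not generalize.

Rewards enter the learners on a normalized scale, ``(r - 50) / 100``, so
the zero prior mean corresponds to the mid-point of the 0-100 payoff
scale; see :func:`normalize_reward`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import COORDS, N_OPTIONS, SQ_EUCLIDEAN, as_flat

#: Default GP observation-noise variance on the normalized scale.  The
#: generative reward noise is N(0, 1) on the 0-100 scale, i.e. variance
#: 1e-4 after dividing by 100; it is held fixed, not estimated.
GP_NOISE_VAR = 1e-4

#: Default BMT prior: mean at the scale mid-point, diffuse variance.
BMT_PRIOR_MEAN = 0.0
BMT_PRIOR_VAR = 5.0


def normalize_reward(r):
    """Map raw rewards (approximately 0-100) onto the modelling scale."""
    return (np.asarray(r, dtype=float) - 50.0) / 100.0


def denormalize_reward(y):
    """Inverse of :func:`normalize_reward`."""
    return np.asarray(y, dtype=float) * 100.0 + 50.0


# ---------------------------------------------------------------------------
# kernels

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family, length-scale, and observation noise for the GP."""

    kind: str = "rbf"  # "rbf" or "shepard"
    lambda_: float = 1.0
    rho: float = 2.0  # Minkowski exponent, shepard only
    noise_var: float = GP_NOISE_VAR

    def __post_init__(self):
        if self.kind not in ("rbf", "shepard"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")
        if not 0 < self.rho <= 2:
            raise ValueError("rho must lie in (0, 2]")
        if not self.noise_var > 0:
            raise ValueError("noise_var must be positive")


def _sq_distance_matrix(spec: KernelSpec) -> np.ndarray:
    if spec.kind == "rbf":
        return SQ_EUCLIDEAN
    diff = np.abs(COORDS[:, None, :] - COORDS[None, :, :]).astype(float)
    d = np.sum(diff**spec.rho, axis=-1) ** (1.0 / spec.rho)
    return d**2


def kernel_matrix(spec: KernelSpec) -> np.ndarray:
    """(64, 64) kernel Gram matrix over all option pairs."""
    return np.exp(-_sq_distance_matrix(spec) / (2.0 * spec.lambda_**2))


def kernel_value(s, s2, spec: KernelSpec) -> float:
    """Kernel similarity between two options; symmetric, in (0, 1]."""
    return float(kernel_matrix(spec)[as_flat(s), as_flat(s2)])


# ---------------------------------------------------------------------------
# belief state

@dataclass(frozen=True)
class BeliefState:
    """Posterior mean and variance over all 64 options, plus history."""

    post_mean: np.ndarray  # (64,)
    post_var: np.ndarray  # (64,), non-negative
    history: tuple = ()  # ordered ((flat option, normalized reward), ...)

    def mean_at(self, option) -> float:
        return float(self.post_mean[as_flat(option)])

    def var_at(self, option) -> float:
        return float(self.post_var[as_flat(option)])


def belief_frame(belief: "BeliefState"):
    """Belief snapshot as a tidy table (option, d1, d2, mean, variance)."""
    import pandas as pd

    from .grid import COORDS

    return pd.DataFrame({
        "option": np.arange(N_OPTIONS),
        "d1": COORDS[:, 0],
        "d2": COORDS[:, 1],
        "mean": belief.post_mean,
        "variance": belief.post_var,
    })


def _history_arrays(history):
    idx = np.array([as_flat(s) for s, _ in history], dtype=np.int64)
    y = np.array([float(r) for _, r in history], dtype=float)
    return idx, y


def gp_posterior(history, spec: KernelSpec) -> BeliefState:
    """Exact GP posterior over all 64 options given noisy observations.

    With an empty history returns the prior (mean 0, variance k(s, s) = 1).
    Otherwise conditions the zero-mean GP on observations via
    ``m = K(*, t) [K(t, t) + noise I]^-1 y`` and the matching variance
    expression. Rewards are expected on the normalized scale.
    """
    if len(history) == 0:
        return BeliefState(np.zeros(N_OPTIONS), np.ones(N_OPTIONS), ())
    idx, y = _history_arrays(history)
    K = kernel_matrix(spec)
    gram = K[np.ix_(idx, idx)] + spec.noise_var * np.eye(len(idx))
    k_star = K[:, idx]  # (64, t)
    sol = np.linalg.solve(gram, np.column_stack([y, k_star.T]))
    mean = k_star @ sol[:, 0]
    var = np.diag(K) - np.einsum("ij,ji->i", k_star, sol[:, 1:])
    return BeliefState(mean, np.maximum(var, 0.0), tuple((int(i), float(v)) for i, v in zip(idx, y)))


def gp_posterior_weights(history, spec: KernelSpec) -> np.ndarray:
    """Weights w = [K + noise I]^-1 y of the similarity-weighted-sum form.

    The posterior mean at any option equals ``sum_i w_i k(s, s_i)`` — the
    kernel-weighted sum over observed inputs, an RBF-network reading of
    GP regression.
    """
    if len(history) == 0:
        raise ValueError("weights are undefined for an empty history")
    idx, y = _history_arrays(history)
    K = kernel_matrix(spec)
    gram = K[np.ix_(idx, idx)] + spec.noise_var * np.eye(len(idx))
    return np.linalg.solve(gram, y)


# ---------------------------------------------------------------------------
# Bayesian Mean Tracker

@dataclass(frozen=True)
class BMTConfig:
    """BMT prior and error variance (the single learning parameter)."""

    theta_eps2: float
    m0: float = BMT_PRIOR_MEAN
    v0: float = BMT_PRIOR_VAR

    def __post_init__(self):
        if not self.theta_eps2 > 0:
            raise ValueError("theta_eps2 must be positive")
        if not self.v0 > 0:
            raise ValueError("v0 must be positive")


@dataclass(frozen=True)
class BMTUpdateTrace:
    kalman_gain: float
    prediction_error: float


def bmt_prior(cfg: BMTConfig) -> BeliefState:
    return BeliefState(
        np.full(N_OPTIONS, cfg.m0, dtype=float),
        np.full(N_OPTIONS, cfg.v0, dtype=float),
        (),
    )


def bmt_update(state: BeliefState, cfg: BMTConfig, chosen, reward: float):
    """One delta-rule update of the chosen option's normal belief.

    The Kalman gain ``G = v / (v + theta_eps2)`` scales the prediction
    error; the chosen option's variance shrinks by ``(1 - G)`` and every
    other option is untouched. Returns the new state and an update trace.
    """
    j = as_flat(chosen)
    v_prev = float(state.post_var[j])
    gain = v_prev / (v_prev + cfg.theta_eps2)
    err = float(reward) - float(state.post_mean[j])
    mean = state.post_mean.copy()
    var = state.post_var.copy()
    mean[j] += gain * err
    var[j] *= 1.0 - gain
    new_state = BeliefState(mean, var, state.history + ((j, float(reward)),))
    return new_state, BMTUpdateTrace(kalman_gain=gain, prediction_error=err)
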