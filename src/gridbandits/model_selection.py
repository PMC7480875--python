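"""Group-level random-effects Bayesian model selection.

Treats the model identity as a random effect: each subject's data are
generated by one of K models, with unknown population frequencies ``r``
given a Dirichlet prior. Variational Bayes estimates the posterior
Dirichlet concentration from per-subject log model evidences (here, the
negated cross-validated out-of-sample log loss). From the posterior we
report:

* the **exceedance probability** ``xp_k`` — the posterior probability that
  model k is more frequent in the population than every other model;
* the **Bayesian omnibus risk** ``BOR`` — the posterior probability that
  all model frequencies are equal (differences arose by chance);
* the **protected exceedance probability**
  ``pxp_k = xp_k (1 - BOR) + BOR / K``, the chance-corrected quantity
  reported for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


@dataclass(frozen=True)
class EvidenceMatrix:
    """Per-subject log model evidences (n_subjects x n_models)."""

    log_evidence: np.ndarray
    models: tuple

    def __post_init__(self):
        ev = np.asarray(self.log_evidence, dtype=float)
        if ev.ndim != 2 or ev.shape[0] < 2 or ev.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 models")
        if not np.isfinite(ev).all():
            raise ValueError("log evidences must be finite")
        if ev.shape[1] != len(self.models):
            raise ValueError("model labels do not match the matrix width")
        object.__setattr__(self, "log_evidence", ev)


@dataclass(frozen=True)
class BMSResult:
    models: tuple
    alpha: np.ndarray  # posterior Dirichlet concentrations
    expected_freq: np.ndarray  # E[r_k]
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    converged: bool


def vb_dirichlet(ev: EvidenceMatrix, alpha0: float = 1.0, tol: float = 1e-8,
                 max_iter: int = 5000):
    """Variational posterior over model frequencies.

    Fixed-point iteration: subject-model responsibilities are proportional
    to ``exp(log evidence + digamma(alpha_k) - digamma(sum alpha))``,
    normalized per subject, and the concentrations are ``alpha0`` plus the
    responsibility column sums. Returns ``(alpha, responsibilities,
    converged)``.
    """
    lme = ev.log_evidence
    n, K = lme.shape
    alpha = np.full(K, alpha0, dtype=float)
    converged = False
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    return alpha, u, converged


def exceedance_prob(alpha: np.ndarray, n_samples: int = 1_000_000,
                    seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities from Dirichlet(alpha).

    The fraction of posterior draws in which each model has the largest
    frequency; sums to 1 up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(np.asarray(alpha, dtype=float), size=int(n_samples))
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / len(winners)


def _dirichlet_entropy(alpha: np.ndarray) -> float:
    a0 = alpha.sum()
    log_b = gammaln(alpha).sum() - gammaln(a0)
    return float(log_b + (a0 - len(alpha)) * digamma(a0)
                 - ((alpha - 1.0) * digamma(alpha)).sum())


def _free_energy(lme: np.ndarray, alpha: np.ndarray, u: np.ndarray,
                 alpha0: float) -> float:
    """Variational free energy of the random-effects model."""
    n, K = lme.shape
    a0_vec = np.full(K, alpha0)
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    expected_joint = (u * lme).sum() + ((u.sum(axis=0) + a0_vec - 1.0) * e_log_r).sum()
    log_b0 = gammaln(a0_vec).sum() - gammaln(a0_vec.sum())
    entropy = _dirichlet_entropy(alpha) - np.sum(u * np.log(np.clip(u, 1e-300, None)))
    return float(expected_joint - log_b0 + entropy)


def omnibus_risk(ev: EvidenceMatrix, alpha: np.ndarray, u: np.ndarray,
                 alpha0: float = 1.0) -> float:
    """Posterior probability that all model frequencies are equal.

    Compares the free energy of the random-effects model (F1) with the
    evidence of the null model in which every subject's model is drawn
    uniformly (F0 = per-subject evidence averaged over models):
    ``BOR = 1 / (1 + exp(F1 - F0))``.
    """
    lme = ev.log_evidence
    K = lme.shape[1]
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(K)))
    f1 = _free_energy(lme, alpha, u, alpha0)
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def protected_xp(xp: np.ndarray, bor: float, n_models: int | None = None) -> np.ndarray:
    """pxp_k = xp_k (1 - BOR) + BOR / K; sums to 1."""
    xp = np.asarray(xp, dtype=float)
    if not np.isclose(xp.sum(), 1.0, atol=1e-6):
        raise ValueError("exceedance probabilities must sum to 1")
    K = n_models if n_models is not None else len(xp)
    return xp * (1.0 - bor) + bor / K


def bms(ev: EvidenceMatrix, alpha0: float = 1.0, n_samples: int = 1_000_000,
        seed: int = 0) -> BMSResult:
    """Full group-level model selection: alpha, xp, BOR, pxp."""
    alpha, u, converged = vb_dirichlet(ev, alpha0=alpha0)
    xp = exceedance_prob(alpha, n_samples=n_samples, seed=seed)
    bor = omnibus_risk(ev, alpha, u, alpha0=alpha0)
    return BMSResult(
        models=tuple(ev.models), alpha=alpha, expected_freq=alpha / alpha.sum(),
        xp=xp, bor=bor, pxp=protected_xp(xp, bor), converged=converged,
    )
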