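"""Choice policy: upper-confidence-bound values through a softmax.

Beliefs become choices in two steps. UCB sampling values each option as
``q(s) = m(s) + beta * v(s)``, where the exploration bonus ``beta`` trades
off exploiting high expected reward against directed exploration of
uncertain options. A softmax with temperature ``tau`` then converts values
to choice probabilities, with larger ``tau`` producing more random,
undirected exploration (``tau -> inf`` is uniform sampling, ``tau -> 0``
is argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

MODELS = ("gp", "gp_shepard", "bmt", "random")


@dataclass(frozen=True)
class ParamSet:
    """A learner + policy parameterization.

    Exactly the free parameters of the named model are set: ``lambda_``
    for the GP variants (plus ``rho`` for the Shepard kernel),
    ``theta_eps2`` for the BMT, and ``beta`` / ``tau`` for every learning
    model. The random model has no parameters.
    """

    model: str
    lambda_: float | None = None
    rho: float | None = None
    theta_eps2: float | None = None
    beta: float | None = None
    tau: float | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "random":
            if any(p is not None for p in (self.lambda_, self.rho, self.theta_eps2, self.beta, self.tau)):
                raise ValueError("the random model has no parameters")
            return
        if self.tau is None or not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.beta is None or self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.model in ("gp", "gp_shepard"):
            if self.lambda_ is None or not self.lambda_ > 0:
                raise ValueError("lambda_ must be positive for GP models")
            if self.theta_eps2 is not None:
                raise ValueError("theta_eps2 is a BMT parameter")
            if self.model == "gp" and self.rho is not None:
                raise ValueError("rho is a Shepard-kernel parameter")
            if self.model == "gp_shepard" and (self.rho is None or not 0 < self.rho <= 2):
                raise ValueError("rho must lie in (0, 2] for the Shepard kernel")
        else:  # bmt
            if self.theta_eps2 is None or not self.theta_eps2 > 0:
                raise ValueError("theta_eps2 must be positive for the BMT")
            if self.lambda_ is not None or self.rho is not None:
                raise ValueError("lambda_/rho are GP parameters")

    @property
    def free_names(self) -> tuple[str, ...]:
        return {
            "gp": ("lambda_", "beta", "tau"),
            "gp_shepard": ("lambda_", "rho", "beta", "tau"),
            "bmt": ("theta_eps2", "beta", "tau"),
            "random": (),
        }[self.model]

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)


def ucb_values(belief, beta: float, uncertainty: str = "variance") -> np.ndarray:
    """Elementwise m + beta * v over the 64 options.

    ``uncertainty`` selects the uncertainty term: the posterior variance
    (the default, matching the value rule as stated) or its square root.
    """
    if uncertainty == "variance":
        u = belief.post_var
    elif uncertainty == "sd":
        u = np.sqrt(belief.post_var)
    else:
        raise ValueError("uncertainty must be 'variance' or 'sd'")
    return belief.post_mean + beta * u


def choice_probabilities(q: np.ndarray, tau: float) -> np.ndarray:
    """Softmax of q / tau with max-subtraction for overflow safety."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    z = np.asarray(q, dtype=float) / tau
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def log_choice_probability(q: np.ndarray, tau: float, chosen: int) -> float:
    """log P(chosen) under the softmax, computed stably."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    z = np.asarray(q, dtype=float) / tau
    return float(z[chosen] - logsumexp(z))


def sample_choice(p: np.ndarray, rng: np.random.Generator) -> int:
    """Seeded categorical draw of a flat option index."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("p is not a probability distribution")
    return int(rng.choice(len(p), p=p / p.sum()))
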