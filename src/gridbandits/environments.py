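"""Correlated reward environments on the 8x8 option grid.

An environment is a draw from a zero-mean Gaussian-process prior with an
RBF kernel over the 64 grid options, min-max normalized so every surface
spans exactly [0, 1]. The generative length-scale controls how strongly
rewards correlate over distance: the study conditions use lambda = 4
("smooth") and lambda = 2 ("rough"), 40 environments per class. Rewards
are observed by scaling the latent surface to a per-round maximum drawn
uniformly from [80, 95] and adding unit-variance Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import MANHATTAN, N_OPTIONS, SQ_EUCLIDEAN, as_flat

LAMBDA_SMOOTH = 4.0
LAMBDA_ROUGH = 2.0
SCALE_MAX_RANGE = (80.0, 95.0)
REWARD_NOISE_SD = 1.0
_JITTER = 1e-8


def class_label(lambda_gen: float) -> str:
    if lambda_gen == LAMBDA_SMOOTH:
        return "smooth"
    if lambda_gen == LAMBDA_ROUGH:
        return "rough"
    return f"lambda={lambda_gen:g}"


@dataclass(frozen=True)
class Environment:
    """A latent reward surface over the 64 options, on the unit scale."""

    means: np.ndarray  # (64,) floats, min 0 and max 1 after normalization
    lambda_gen: float
    env_class: str
    env_id: str
    seed: int

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        if means.shape != (N_OPTIONS,):
            raise ValueError(f"means must have shape ({N_OPTIONS},), got {means.shape}")
        object.__setattr__(self, "means", means)

    def mean_at(self, option) -> float:
        return float(self.means[as_flat(option)])


@dataclass(frozen=True)
class RoundSpec:
    """Per-round reward scaling and bonus flag."""

    env_id: str
    round_index: int
    scale_max: float
    is_bonus: bool = False

    def __post_init__(self):
        lo, hi = SCALE_MAX_RANGE
        if not lo <= self.scale_max <= hi:
            raise ValueError(f"scale_max {self.scale_max} outside [{lo}, {hi}]")


def sample_environment(lambda_gen: float, seed: int, env_id: str | None = None) -> Environment:
    """Draw one environment from the GP prior with length-scale ``lambda_gen``.

    The 64-dimensional multivariate normal has zero mean and covariance
    exp(-d^2 / (2 lambda^2)) over all grid pairs (Euclidean d, raw grid
    units), with a small diagonal jitter for positive-definiteness. The
    draw is min-max normalized to [0, 1]. Deterministic given the seed.
    """
    if not lambda_gen > 0:
        raise ValueError(f"lambda_gen must be positive, got {lambda_gen}")
    cov = np.exp(-SQ_EUCLIDEAN / (2.0 * lambda_gen**2))
    chol = np.linalg.cholesky(cov + _JITTER * np.eye(N_OPTIONS))
    rng = np.random.default_rng(seed)
    raw = chol @ rng.standard_normal(N_OPTIONS)
    lo, hi = raw.min(), raw.max()
    means = (raw - lo) / (hi - lo)
    return Environment(
        means=means,
        lambda_gen=float(lambda_gen),
        env_class=class_label(lambda_gen),
        env_id=env_id if env_id is not None else f"{class_label(lambda_gen)}-{seed}",
        seed=int(seed),
    )


def generate_environment_set(lambda_gen: float, n: int = 40, seed: int = 0) -> list[Environment]:
    """Generate ``n`` distinct seeded environments of one class.

    Per-environment seeds are derived deterministically from the master
    seed via :class:`numpy.random.SeedSequence`, so sets are reproducible
    and individual members can be regenerated from their stored seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    cls = class_label(lambda_gen)
    return [
        sample_environment(lambda_gen, int(s), env_id=f"{cls}-{seed}-{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


def observe_reward(env: Environment, spec: RoundSpec, option, rng: np.random.Generator) -> float:
    """One noisy reward observation: mean * scale_max + N(0, 1) noise."""
    j = as_flat(option)
    return float(env.means[j] * spec.scale_max + rng.normal(0.0, REWARD_NOISE_SD))


def draw_scale_max(rng: np.random.Generator) -> float:
    lo, hi = SCALE_MAX_RANGE
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# persistence

def save_environments(envs: list[Environment], path) -> None:
    """Write a set of environments to JSON (exact float round-trip)."""
    payload = [
        {
            "env_id": e.env_id,
            "class": e.env_class,
            "lambda": e.lambda_gen,
            "seed": e.seed,
            "means": [float(x) for x in e.means],
        }
        for e in envs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_environments(path) -> list[Environment]:
    payload = json.loads(Path(path).read_text())
    return [
        Environment(
            means=np.array(item["means"], dtype=float),
            lambda_gen=float(item["lambda"]),
            env_class=item["class"],
            env_id=item["env_id"],
            seed=int(item["seed"]),
        )
        for item in payload
    ]


# ---------------------------------------------------------------------------
# characterization

def empirical_correlogram(envs: list[Environment]) -> pd.DataFrame:
    """Across-environment reward correlation by Manhattan distance.

    For each distance bin, pools all ordered option pairs at that distance
    across environments and reports the Pearson correlation of their mean
    rewards. Distance 0 is 1 by construction; smoother classes decay more
    slowly. Degenerate (constant-surface) inputs yield NaN.
    """
    if len(envs) < 1:
        raise ValueError("need at least one environment")
    means = np.stack([e.means for e in envs])  # (E, 64)
    rows = []
    for d in range(int(MANHATTAN.max()) + 1):
        ii, jj = np.nonzero(MANHATTAN == d)
        x = means[:, ii].ravel()
        y = means[:, jj].ravel()
        if x.std() == 0 or y.std() == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(x, y)[0, 1])
        rows.append({"distance": d, "correlation": corr, "n_pairs": len(ii) * len(envs)})
    return pd.DataFrame(rows)
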