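"""Descriptive and model-validation analyses of choice datasets.

Pure functions of the choice-data schema: within-round learning curves,
search-distance statistics against the 5.25 chance baseline, mean-squared
differences between aggregate curves, and out-of-task bonus-round
predictions that compare a fitted learner's posterior over the 10 judged
options with the recorded reward estimates and confidence ratings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ChoiceDataset
from .grid import MANHATTAN, chance_manhattan_distance
from .learners import BMTConfig, KernelSpec, bmt_prior, bmt_update, denormalize_reward, gp_posterior, normalize_reward
from .policy import ParamSet

CHANCE_DISTANCE = chance_manhattan_distance()  # 5.25 on the 8x8 grid


@dataclass(frozen=True)
class SearchStats:
    """Per-participant consecutive-choice distance summary."""

    participant_id: str
    task: str
    mean_distance: float
    chance_distance: float
    corr_prev_reward_pearson: float
    corr_prev_reward_kendall: float
    distance_by_reward_bin: pd.DataFrame


def learning_curves(datasets, include_bonus: bool = False) -> pd.DataFrame:
    """Mean reward per trial index, aggregated over rounds and participants.

    Rewards are averaged within participant first (over the non-bonus
    rounds unless ``include_bonus``), then across participants; the
    standard error is across participants. Columns: trial, mean_reward,
    se, n.
    """
    if not datasets:
        raise ValueError("no datasets given")
    per_participant = []
    for ds in datasets:
        rounds = ds.rounds if include_bonus else ds.training_rounds()
        per_participant.append(np.mean([r.reward for r in rounds], axis=0))
    mat = np.stack(per_participant)  # (P, T)
    n = mat.shape[0]
    se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    return pd.DataFrame({
        "trial": np.arange(1, mat.shape[1] + 1),
        "mean_reward": mat.mean(axis=0),
        "se": se,
        "n": n,
    })


def per_round_curve(datasets) -> pd.DataFrame:
    """Mean reward per round index (across-round learning)."""
    rows = []
    for ds in datasets:
        for r in ds.training_rounds():
            rows.append((ds.participant_id, r.spec.round_index, float(r.reward.mean())))
    df = pd.DataFrame(rows, columns=["participant_id", "round", "mean_reward"])
    return df.groupby("round", as_index=False)["mean_reward"].mean()


def curve_mse(curve_a: pd.DataFrame, curve_b: pd.DataFrame) -> float:
    """Mean squared difference between two per-trial mean-reward curves."""
    a = np.asarray(curve_a["mean_reward"] if hasattr(curve_a, "columns") else curve_a, dtype=float)
    b = np.asarray(curve_b["mean_reward"] if hasattr(curve_b, "columns") else curve_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("curves must have equal length")
    return float(np.mean((a - b) ** 2))


def search_distances(dataset: ChoiceDataset, n_bins: int = 10) -> SearchStats:
    """Manhattan distances between consecutive within-round selections.

    Also correlates the previous trial's reward with the next step's
    distance (Pearson and Kendall): generalizing searchers step further
    after poor outcomes, giving negative correlations.
    """
    dists, prev_rewards = [], []
    for r in dataset.training_rounds():
        d = MANHATTAN[r.chosen[:-1], r.chosen[1:]]
        dists.append(d)
        prev_rewards.append(r.reward[:-1])
    d = np.concatenate(dists).astype(float)
    pr = np.concatenate(prev_rewards)
    if d.std() == 0 or pr.std() == 0:
        pearson = kendall = np.nan
    else:
        pearson = float(stats.pearsonr(pr, d)[0])
        kendall = float(stats.kendalltau(pr, d)[0])
    bins = pd.cut(pr, bins=n_bins)
    table = (pd.DataFrame({"prev_reward_bin": bins, "distance": d})
             .groupby("prev_reward_bin", observed=True, as_index=False)["distance"]
             .mean())
    return SearchStats(
        participant_id=dataset.participant_id, task=dataset.task,
        mean_distance=float(d.mean()), chance_distance=CHANCE_DISTANCE,
        corr_prev_reward_pearson=pearson, corr_prev_reward_kendall=kendall,
        distance_by_reward_bin=table,
    )


def cohort_search_table(datasets) -> pd.DataFrame:
    """One row of search statistics per dataset."""
    rows = []
    for ds in datasets:
        s = search_distances(ds)
        rows.append((s.participant_id, s.task, ds.env_class, s.mean_distance,
                     s.corr_prev_reward_pearson, s.corr_prev_reward_kendall))
    return pd.DataFrame(rows, columns=[
        "participant_id", "task", "env_class", "mean_distance",
        "corr_prev_reward_pearson", "corr_prev_reward_kendall"])


def bonus_round_predictions(params: ParamSet, dataset: ChoiceDataset,
                            rescale: str = "midpoint") -> pd.DataFrame:
    """Out-of-task model predictions for the bonus-round judgments.

    Conditions the learner (at the given parameters, normally estimated
    from rounds 1-9) on the bonus round's first 15 observations and
    predicts reward and uncertainty for each judged option. Predicted
    rewards are mapped back to the 0-100 judgment scale either through the
    inverse of the modelling normalization (``midpoint``) or by min-max
    aligning predictions with the observed rewards of those 15 trials
    (``minmax``). BMT predictions are constant across unobserved options,
    so its prediction-judgment correlation is undefined (NaN).
    """
    if dataset.judgments is None:
        raise ValueError("dataset has no bonus-round judgments")
    bonus = dataset.bonus_round()
    k = 15
    y = normalize_reward(bonus.reward[:k])
    if params.model == "bmt":
        state = bmt_prior(BMTConfig(theta_eps2=params.theta_eps2))
        for j, yy in zip(bonus.chosen[:k], y):
            state, _ = bmt_update(state, BMTConfig(theta_eps2=params.theta_eps2),
                                  int(j), float(yy))
        belief = state
    elif params.model in ("gp", "gp_shepard"):
        kind = "shepard" if params.model == "gp_shepard" else "rbf"
        spec = KernelSpec(kind=kind, lambda_=params.lambda_,
                          rho=params.rho if params.rho is not None else 2.0)
        belief = gp_posterior(list(zip(bonus.chosen[:k].tolist(), y.tolist())), spec)
    else:
        raise ValueError(f"no belief model for {params.model!r}")

    opts = dataset.judgments.options
    pred_mean = belief.post_mean[opts]
    pred_var = belief.post_var[opts]
    if rescale == "midpoint":
        pred_reward = np.clip(denormalize_reward(pred_mean), 1, 100)
    elif rescale == "minmax":
        obs = bonus.reward[:k]
        m = belief.post_mean
        span = m.max() - m.min()
        if span == 0:
            pred_reward = np.full(len(opts), obs.mean())
        else:
            pred_reward = (pred_mean - m.min()) / span * (obs.max() - obs.min()) + obs.min()
    else:
        raise ValueError("rescale must be 'midpoint' or 'minmax'")
    return pd.DataFrame({
        "option": opts,
        "predicted_reward": pred_reward,
        "predicted_variance": pred_var,
        "estimate": dataset.judgments.estimate,
        "confidence": dataset.judgments.confidence,
    })


def bonus_round_correlations(params: ParamSet, dataset: ChoiceDataset) -> dict:
    """Per-participant judgment/prediction agreement.

    Pearson correlation between predicted and judged reward, and Spearman
    rank correlation between stated confidence and predicted variance
    (expected negative: confidence tracks low uncertainty). NaN where a
    constant predictor makes the correlation undefined.
    """
    df = bonus_round_predictions(params, dataset)
    out = {}
    if df["predicted_reward"].std() == 0 or df["estimate"].std() == 0:
        out["reward_correlation"] = np.nan
    else:
        out["reward_correlation"] = float(
            stats.pearsonr(df["predicted_reward"], df["estimate"])[0])
    if df["predicted_variance"].std() == 0 or df["confidence"].std() == 0:
        out["confidence_variance_rank_correlation"] = np.nan
    else:
        out["confidence_variance_rank_correlation"] = float(
            stats.spearmanr(df["confidence"], df["predicted_variance"])[0])
    return out
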