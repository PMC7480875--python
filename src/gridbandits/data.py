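"""Round-structured choice data and its CSV schema.

A :class:`ChoiceDataset` holds one participant-or-agent session on one
task: 10 rounds of 20 trials, each trial a random start stimulus, a
chosen option, and a noisy reward; round 10 is the bonus round carrying a
:class:`JudgmentSet` of 10 reward/confidence judgments for unobserved
options. Datasets round-trip through two tidy CSV tables (choices and
judgments) so every analysis is a pure function of the on-disk schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environments import RoundSpec
from .grid import N_OPTIONS, N_SIDE, coord
from .policy import ParamSet

TASKS = ("spatial", "conceptual")
ENV_CLASSES = ("smooth", "rough")
TASK_ORDERS = ("first", "second")

N_ROUNDS = 10
N_TRIALS = 20
BONUS_JUDGMENT_TRIAL = 15  # judgments elicited after this many choices
N_JUDGMENTS = 10

CHOICE_COLUMNS = [
    "participant_id", "task", "env_class", "task_order",
    "round", "trial", "start_d1", "start_d2", "d1", "d2", "reward", "scale_max",
]
JUDGMENT_COLUMNS = ["participant_id", "task", "d1", "d2", "estimate", "confidence"]


@dataclass(frozen=True)
class RoundData:
    """One round: its spec plus per-trial arrays (flat option indices)."""

    spec: RoundSpec
    start: np.ndarray  # (T,) flat indices of the random start stimulus
    chosen: np.ndarray  # (T,) flat indices of selections
    reward: np.ndarray  # (T,) raw observed rewards (approximately 0-100)

    def __post_init__(self):
        object.__setattr__(self, "start", np.asarray(self.start, dtype=np.int64))
        object.__setattr__(self, "chosen", np.asarray(self.chosen, dtype=np.int64))
        object.__setattr__(self, "reward", np.asarray(self.reward, dtype=float))

    @property
    def n_trials(self) -> int:
        return len(self.chosen)


@dataclass(frozen=True)
class JudgmentSet:
    """Bonus-round judgments for 10 options unobserved in trials 1-15."""

    options: np.ndarray  # (10,) flat indices
    estimate: np.ndarray  # (10,) integers in [1, 100]
    confidence: np.ndarray  # (10,) integers in [0, 10]
    forced_choice: int  # flat index of the judged option then selected

    def __post_init__(self):
        object.__setattr__(self, "options", np.asarray(self.options, dtype=np.int64))
        object.__setattr__(self, "estimate", np.asarray(self.estimate, dtype=np.int64))
        object.__setattr__(self, "confidence", np.asarray(self.confidence, dtype=np.int64))


@dataclass(frozen=True)
class ChoiceDataset:
    """One participant/agent on one task; see module docstring."""

    participant_id: str
    task: str
    env_class: str
    task_order: str
    rounds: tuple
    judgments: JudgmentSet | None = None
    params: ParamSet | None = None  # generating parameters, synthetic only

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def training_rounds(self) -> list[RoundData]:
        """Rounds 1-9 — the bonus round is excluded from all model fitting."""
        return [r for r in self.rounds if not r.spec.is_bonus]

    def bonus_round(self) -> RoundData:
        bonus = [r for r in self.rounds if r.spec.is_bonus]
        if len(bonus) != 1:
            raise ValueError("dataset does not contain exactly one bonus round")
        return bonus[0]


def validate(ds: ChoiceDataset, n_rounds: int = N_ROUNDS, n_trials: int = N_TRIALS) -> None:
    """Schema check: counts, coordinate ranges, bonus-round structure."""
    if ds.task not in TASKS:
        raise ValueError(f"unknown task {ds.task!r}")
    if ds.env_class not in ENV_CLASSES:
        raise ValueError(f"unknown env_class {ds.env_class!r}")
    if ds.task_order not in TASK_ORDERS:
        raise ValueError(f"unknown task_order {ds.task_order!r}")
    if len(ds.rounds) != n_rounds:
        raise ValueError(f"expected {n_rounds} rounds, got {len(ds.rounds)}")
    env_ids = [r.spec.env_id for r in ds.rounds]
    if len(set(env_ids)) != len(env_ids):
        raise ValueError("environments must be drawn without replacement")
    for i, rnd in enumerate(ds.rounds, start=1):
        if rnd.spec.round_index != i:
            raise ValueError("rounds out of order")
        if rnd.spec.is_bonus != (i == n_rounds):
            raise ValueError("exactly the last round must be the bonus round")
        if rnd.n_trials != n_trials:
            raise ValueError(f"round {i} has {rnd.n_trials} trials, expected {n_trials}")
        for arr in (rnd.start, rnd.chosen):
            if arr.min() < 0 or arr.max() >= N_OPTIONS:
                raise ValueError("option index outside the grid")
    if ds.judgments is not None:
        j = ds.judgments
        if len(j.options) != N_JUDGMENTS or len(set(j.options.tolist())) != N_JUDGMENTS:
            raise ValueError(f"expected {N_JUDGMENTS} distinct judged options")
        seen = set(ds.bonus_round().chosen[:BONUS_JUDGMENT_TRIAL].tolist())
        if seen & set(j.options.tolist()):
            raise ValueError("judged options must be unobserved in trials 1-15")
        if j.estimate.min() < 1 or j.estimate.max() > 100:
            raise ValueError("estimates must lie in [1, 100]")
        if j.confidence.min() < 0 or j.confidence.max() > 10:
            raise ValueError("confidence must lie in [0, 10]")
        if j.forced_choice not in set(j.options.tolist()):
            raise ValueError("forced choice must be one of the judged options")


# ---------------------------------------------------------------------------
# tidy-frame conversion

def choices_frame(datasets) -> pd.DataFrame:
    """Stack datasets into the tidy choice table (one row per trial)."""
    rows = []
    for ds in datasets:
        for rnd in ds.rounds:
            for t in range(rnd.n_trials):
                s1, s2 = coord(int(rnd.start[t]))
                d1, d2 = coord(int(rnd.chosen[t]))
                rows.append((
                    ds.participant_id, ds.task, ds.env_class, ds.task_order,
                    rnd.spec.round_index, t + 1, s1, s2, d1, d2,
                    float(rnd.reward[t]), rnd.spec.scale_max,
                ))
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def judgments_frame(datasets) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        if ds.judgments is None:
            continue
        for opt, est, conf in zip(ds.judgments.options, ds.judgments.estimate, ds.judgments.confidence):
            d1, d2 = coord(int(opt))
            rows.append((ds.participant_id, ds.task, d1, d2, int(est), int(conf)))
    return pd.DataFrame(rows, columns=JUDGMENT_COLUMNS)


def datasets_from_frames(choices: pd.DataFrame, judgments: pd.DataFrame | None = None):
    """Rebuild :class:`ChoiceDataset` objects from the tidy tables.

    Round metadata (env ids, bonus flag) is reconstructed positionally:
    round indices are 1-based and the highest round of a session is the
    bonus round. Generating parameters and the bonus-round forced choice
    are not part of the CSV schema; the forced choice defaults to the
    first judged option as a placeholder.
    """
    datasets = []
    for (pid, task), grp in choices.groupby(["participant_id", "task"], sort=False):
        rounds = []
        n_rounds = int(grp["round"].max())
        for r in range(1, n_rounds + 1):
            g = grp[grp["round"] == r].sort_values("trial")
            spec = RoundSpec(
                env_id=f"{pid}-{task}-r{r}",
                round_index=r,
                scale_max=float(g["scale_max"].iloc[0]),
                is_bonus=(r == n_rounds),
            )
            rounds.append(RoundData(
                spec=spec,
                start=(g["start_d1"] * N_SIDE + g["start_d2"]).to_numpy(),
                chosen=(g["d1"] * N_SIDE + g["d2"]).to_numpy(),
                reward=g["reward"].to_numpy(),
            ))
        js = None
        if judgments is not None:
            jg = judgments[(judgments["participant_id"] == pid) & (judgments["task"] == task)]
            if len(jg):
                js = JudgmentSet(
                    options=(jg["d1"] * N_SIDE + jg["d2"]).to_numpy(),
                    estimate=jg["estimate"].to_numpy(),
                    confidence=jg["confidence"].to_numpy(),
                    forced_choice=int(jg["d1"].iloc[0] * N_SIDE + jg["d2"].iloc[0]),
                )
        datasets.append(ChoiceDataset(
            participant_id=str(pid),
            task=str(task),
            env_class=str(grp["env_class"].iloc[0]),
            task_order=str(grp["task_order"].iloc[0]),
            rounds=tuple(rounds),
            judgments=js,
        ))
    return datasets
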