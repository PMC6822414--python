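"""Random-utility choice simulation: the synthetic-data generator.

Emulates an unlabelled pilot experiment: each respondent answers every task,
utilities are linear in the encoded attributes plus i.i.d. standard Gumbel
noise (drawn as -ln(-ln(u))), the chosen alternative is the utility argmax,
and full best-to-worst ranks are recorded.  An optional normal
random-coefficient layer produces mixed-logit (panel) structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import Design, task_matrix
from .schema import AttributeSet

__all__ = [
    "ChoiceDataset",
    "SimulationConfig",
    "DataError",
    "simulate_choices",
    "analytic_choice_probabilities",
]

#: Non-parameter columns of the long-format table, in order.
ID_COLUMNS = ["respondent_id", "task_id", "alt_id", "chosen", "rank", "is_optout"]


class DataError(ValueError):
    """Raised when a choice dataset violates its structural invariants."""


@dataclass
class ChoiceDataset:
    """Long-format choices: one row per respondent x task x alternative.

    ``table`` holds the id columns (:data:`ID_COLUMNS`, ``rank`` optional)
    followed by one encoded column per utility parameter in ``param_names``.
    """

    table: pd.DataFrame
    param_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.param_names = tuple(self.param_names)
        self.validate()

    def validate(self) -> None:
        t = self.table
        required = [c for c in ID_COLUMNS if c != "rank"] + list(self.param_names)
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        if len(t) == 0:
            raise DataError("empty choice dataset")
        keys = t[["respondent_id", "task_id", "alt_id"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise DataError(f"duplicate (respondent, task, alt) key: {tuple(dup)}")
        chosen_per_obs = t.groupby(["respondent_id", "task_id"])["chosen"].sum()
        bad = chosen_per_obs[chosen_per_obs != 1]
        if len(bad):
            resp, task = bad.index[0]
            raise DataError(
                f"each (respondent, task) needs exactly one chosen row; "
                f"respondent {resp} task {task} has {int(bad.iloc[0])}")
        if self.has_ranks:
            ordered = t.sort_values(["respondent_id", "task_id", "rank"], kind="stable")
            expected = ordered.groupby(["respondent_id", "task_id"]).cumcount() + 1
            bad = ordered["rank"].to_numpy() != expected.to_numpy()
            if bad.any():
                row = ordered[bad].iloc[0]
                raise DataError(
                    f"respondent {row['respondent_id']} task {row['task_id']}: "
                    f"ranks are not a permutation of 1..n_alts")
            top = t[t["rank"] == 1]
            mismatched = top[top["chosen"] != 1]
            if len(mismatched):
                row = mismatched.iloc[0]
                raise DataError(
                    f"respondent {row['respondent_id']} task {row['task_id']}: "
                    f"rank 1 is not the chosen row")

    @property
    def has_ranks(self) -> bool:
        return "rank" in self.table.columns

    @property
    def n_obs(self) -> int:
        """Choice observations = distinct (respondent, task) pairs."""
        return self.table.groupby(["respondent_id", "task_id"]).ngroups

    @property
    def n_respondents(self) -> int:
        return self.table["respondent_id"].nunique()

    @property
    def k(self) -> int:
        return len(self.param_names)

    def design_matrix(self) -> np.ndarray:
        return self.table[list(self.param_names)].to_numpy(dtype=float)

    def drop_optout(self) -> tuple["ChoiceDataset", int]:
        """Forced-choice view: remove opt-out rows, drop tasks where the
        opt-out was chosen, and drop the ASC column.  Returns the reduced
        dataset and the number of dropped tasks."""
        t = self.table
        chose_oo = t[(t["is_optout"] == 1) & (t["chosen"] == 1)][["respondent_id", "task_id"]]
        n_dropped = len(chose_oo)
        keep = t.merge(chose_oo.assign(_drop=1), on=["respondent_id", "task_id"], how="left")
        keep = keep[keep["_drop"].isna()].drop(columns="_drop")
        keep = keep[keep["is_optout"] == 0].copy()
        if len(keep) == 0:
            raise DataError("forced-choice reduction removed every row")
        params = tuple(n for n in self.param_names if n != "optout")
        if "rank" in keep.columns:
            keep = keep.drop(columns="rank")  # ranks no longer a 1..J permutation
        return ChoiceDataset(table=keep.reset_index(drop=True), param_names=params), n_dropped


@dataclass
class SimulationConfig:
    """True data-generating parameters for the simulator."""

    beta_true: np.ndarray
    n_respondents: int
    seed: int = 0
    rank_depth: int | None = None  # None -> full ranking
    random_sds: Mapping[str, float] | None = None  # normal random-coefficient layer
    unacceptable_threshold: float | None = None  # optional flag column (non-standard)

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if not np.all(np.isfinite(self.beta_true)):
            raise DataError("beta_true must be finite")
        if self.n_respondents < 1:
            raise DataError("n_respondents must be >= 1")


def analytic_choice_probabilities(design: Design, beta: np.ndarray) -> np.ndarray:
    """Per-task MNL choice probabilities softmax(X beta); rows sum to 1.

    Utilities are max-shifted before exponentiation, so probabilities are
    invariant to adding any constant to all of a task's utilities.
    """
    beta = np.asarray(beta, dtype=float)
    k = design.attrs.k
    if beta.shape != (k,):
        raise DataError(f"beta must have length {k}, got {beta.shape}")
    out = np.empty((design.n_tasks, design.n_alts))
    for i, task in enumerate(design.tasks):
        v = task_matrix(task, design.attrs) @ beta
        v -= v.max()
        e = np.exp(v)
        out[i] = e / e.sum()
    return out


def simulate_choices(design: Design, cfg: SimulationConfig) -> ChoiceDataset:
    """Draw one choice (and ranking) per respondent x task under the config.

    Utility of alternative j in task s for respondent n is
    ``x_sj . beta_n + gumbel``, with ``beta_n = beta_true`` plus optional
    normal deviations for attributes listed in ``cfg.random_sds``.
    """
    attrs: AttributeSet = design.attrs
    k = attrs.k
    if cfg.beta_true.shape != (k,):
        raise DataError(f"beta_true must have length {k}, got {cfg.beta_true.shape}")
    rng = np.random.default_rng(cfg.seed)
    param_names = attrs.param_names
    n_alts = design.n_alts
    xs = np.stack([task_matrix(t, attrs) for t in design.tasks])  # (S, J, K)

    sds = np.zeros(k)
    if cfg.random_sds:
        unknown = set(cfg.random_sds) - set(param_names)
        if unknown:
            raise DataError(f"random_sds names not in parameter list: {sorted(unknown)}")
        for name, sd in cfg.random_sds.items():
            if sd < 0:
                raise DataError(f"random_sds[{name!r}] must be >= 0")
            sds[param_names.index(name)] = sd

    n = cfg.n_respondents
    n_tasks = design.n_tasks
    if cfg.random_sds:
        beta_n = cfg.beta_true + sds * rng.standard_normal((n, k))  # (N, K)
        v = np.einsum("sjk,nk->nsj", xs, beta_n)
    else:
        v = np.broadcast_to(np.einsum("sjk,k->sj", xs, cfg.beta_true), (n, n_tasks, n_alts))
    u = rng.uniform(size=(n, n_tasks, n_alts))
    util = v - np.log(-np.log(u))
    order = np.argsort(-util, axis=2, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(1, n_alts + 1)[None, None, :], axis=2)

    task_ids = np.array([t.task_id for t in design.tasks])
    is_oo = np.array([int(oo) for _, oo in design.tasks[0].alternatives])
    table = pd.DataFrame({
        "respondent_id": np.repeat(np.arange(1, n + 1), n_tasks * n_alts),
        "task_id": np.tile(np.repeat(task_ids, n_alts), n),
        "alt_id": np.tile(np.arange(1, n_alts + 1), n * n_tasks),
        "chosen": (rank == 1).astype(int).ravel(),
        "rank": rank.ravel(),
        "is_optout": np.tile(is_oo, n * n_tasks),
    })
    flat_x = np.tile(xs.reshape(n_tasks * n_alts, k), (n, 1))
    for j, name in enumerate(param_names):
        table[name] = flat_x[:, j]
    if cfg.unacceptable_threshold is not None:
        # Non-standard convenience flag: systematic utility below a cutoff.
        table["unacceptable"] = (v.ravel() < cfg.unacceptable_threshold).astype(int)
    if cfg.rank_depth is not None and cfg.rank_depth < n_alts:
        table = table.drop(columns="rank")
    return ChoiceDataset(table=table, param_names=param_names)
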