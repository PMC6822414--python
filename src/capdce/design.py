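"""D-efficient choice-design generation under point priors.

The search is a seeded multi-start coordinate-exchange over a full-factorial
candidate set: every (task, alternative, attribute) position is visited in
order, every level is tried, and an exchange is kept only when it strictly
lowers the D-error.  The opt-out alternative is held fixed (all-zero row with
an ASC) and never exchanged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .schema import AttributeSet

__all__ = [
    "ChoiceTask",
    "Design",
    "DesignScore",
    "DesignConfigError",
    "full_candidate_set",
    "task_matrix",
    "mnl_information",
    "d_error",
    "optimize_design",
    "random_design",
    "design_diagnostics",
]


class DesignConfigError(ValueError):
    """Raised for infeasible design requests."""


@dataclass
class ChoiceTask:
    """One choice task: an ordered list of (assignment, is_optout) alternatives."""

    task_id: int
    alternatives: list[tuple[dict[str, int] | None, bool]]

    @property
    def n_alts(self) -> int:
        return len(self.alternatives)


@dataclass
class Design:
    """A full choice design (opt-out, when present, is the last alternative)."""

    tasks: list[ChoiceTask]
    attrs: AttributeSet

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_alts(self) -> int:
        return self.tasks[0].n_alts

    def validate(self) -> None:
        n_alts = self.n_alts
        for t in self.tasks:
            if t.n_alts != n_alts:
                raise DesignConfigError(f"task {t.task_id}: {t.n_alts} alternatives, expected {n_alts}")
            optouts = [i for i, (_, oo) in enumerate(t.alternatives) if oo]
            if optouts and optouts != [n_alts - 1]:
                raise DesignConfigError(f"task {t.task_id}: opt-out must be the single last alternative")
            assigns = [tuple(sorted(a.items())) for a, oo in t.alternatives if not oo]
            if len(set(assigns)) != len(assigns):
                raise DesignConfigError(f"task {t.task_id}: duplicate non-opt-out alternatives")


@dataclass
class DesignScore:
    """D-error and the Fisher information it derives from."""

    d_error: float
    information: np.ndarray
    priors: np.ndarray
    trace: list[float] = field(default_factory=list)


def full_candidate_set(attrs: AttributeSet) -> list[dict[str, int]]:
    """All full-factorial profiles as attribute-name -> level-index maps."""
    names = [a.name for a in attrs.attributes]
    grids = [range(a.n_levels) for a in attrs.attributes]
    return [dict(zip(names, combo)) for combo in itertools.product(*grids)]


def task_matrix(task: ChoiceTask, attrs: AttributeSet) -> np.ndarray:
    """Encoded (n_alts, K) matrix for one task."""
    return np.vstack([attrs.encode(a, is_optout=oo) for a, oo in task.alternatives])


def _cost_scale(attrs: AttributeSet, rescale_cost: bool) -> np.ndarray:
    """Per-parameter column scaling; monetary codes are divided by 1000 for
    conditioning when ``rescale_cost`` is set (the D-error changes by a
    constant factor only, so rankings between designs are unaffected)."""
    scale = np.ones(attrs.k)
    if rescale_cost and attrs.cost_attribute is not None:
        pos = 0
        for a in attrs.attributes:
            if a.is_cost:
                scale[pos : pos + a.n_params] = 1e-3
            pos += a.n_params
    return scale


def mnl_information(design: Design, priors: np.ndarray, *, rescale_cost: bool = False) -> np.ndarray:
    """MNL Fisher information at the priors: sum over tasks of
    X'(diag(p) - pp')X with p the softmax choice probabilities."""
    priors = np.asarray(priors, dtype=float)
    k = design.attrs.k
    if priors.shape != (k,):
        raise DesignConfigError(f"priors must have length {k}, got {priors.shape}")
    scale = _cost_scale(design.attrs, rescale_cost)
    info = np.zeros((k, k))
    for task in design.tasks:
        x = task_matrix(task, design.attrs) * scale
        v = x @ (priors / scale)
        v -= v.max()
        p = np.exp(v)
        p /= p.sum()
        xp = x * p[:, None]
        info += x.T @ xp - np.outer(xp.sum(axis=0), p @ x)
    return 0.5 * (info + info.T)


def d_error(design: Design, priors: np.ndarray, *, rescale_cost: bool = False) -> float:
    """det(I^-1)^(1/K); returns +inf (not an exception) when I is singular."""
    info = mnl_information(design, priors, rescale_cost=rescale_cost)
    k = info.shape[0]
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return math.inf
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        return math.inf
    return math.exp(-logdet / k)


def _random_task(candidates: list[dict[str, int]], n_nonoptout: int, include_optout: bool,
                 rng: np.random.Generator, task_id: int) -> ChoiceTask:
    idx = rng.choice(len(candidates), size=n_nonoptout, replace=False)
    alts: list[tuple[dict[str, int] | None, bool]] = [(dict(candidates[i]), False) for i in idx]
    if include_optout:
        alts.append((None, True))
    return ChoiceTask(task_id=task_id, alternatives=alts)


def random_design(attrs: AttributeSet, n_tasks: int, n_nonoptout_alts: int,
                  rng: np.random.Generator) -> Design:
    """Uniform random design of the requested shape (baseline / start point)."""
    candidates = full_candidate_set(attrs)
    if n_nonoptout_alts > len(candidates):
        raise DesignConfigError(
            f"requested {n_nonoptout_alts} distinct alternatives per task but only "
            f"{len(candidates)} profiles exist")
    tasks = [_random_task(candidates, n_nonoptout_alts, attrs.optout_asc, rng, t + 1)
             for t in range(n_tasks)]
    return Design(tasks=tasks, attrs=attrs)


def _has_duplicate(task: ChoiceTask) -> bool:
    assigns = [tuple(sorted(a.items())) for a, oo in task.alternatives if not oo]
    return len(set(assigns)) != len(assigns)


def optimize_design(attrs: AttributeSet, n_tasks: int, n_nonoptout_alts: int,
                    priors: np.ndarray | None = None, seed: int = 0,
                    n_starts: int = 5, max_passes: int = 25) -> tuple[Design, DesignScore]:
    """Coordinate-exchange D-error minimization.

    For each of ``n_starts`` random starting designs, sweep over every
    (task, alternative, attribute) slot trying every level; keep strictly
    improving exchanges (first-improving level wins at ties) until a full
    pass makes no change or ``max_passes`` is hit.  Deterministic given
    ``seed``.  Returns the best design across starts with its score; the
    score's ``trace`` records the accepted D-error path of the winning start.
    """
    if n_tasks < 1:
        raise DesignConfigError("n_tasks must be >= 1")
    priors = attrs.default_priors() if priors is None else np.asarray(priors, dtype=float)
    if priors.shape != (attrs.k,):
        raise DesignConfigError(f"priors must have length {attrs.k}, got {priors.shape}")
    rng = np.random.default_rng(seed)
    best: tuple[float, Design, list[float]] | None = None

    for _ in range(max(1, n_starts)):
        design = random_design(attrs, n_tasks, n_nonoptout_alts, rng)
        current = d_error(design, priors, rescale_cost=True)
        trace = [current]
        for _pass in range(max_passes):
            improved = False
            for task in design.tasks:
                for alt_i, (assignment, is_oo) in enumerate(task.alternatives):
                    if is_oo:
                        continue
                    for attr in attrs.attributes:
                        original = assignment[attr.name]
                        for lev in range(attr.n_levels):
                            if lev == original:
                                continue
                            assignment[attr.name] = lev
                            if _has_duplicate(task):
                                continue
                            cand = d_error(design, priors, rescale_cost=True)
                            if cand < current:
                                current = cand
                                original = lev
                                trace.append(current)
                                improved = True
                        assignment[attr.name] = original
            if not improved:
                break
        if best is None or current < best[0]:
            best = (current, design, trace)

    assert best is not None
    _, design, trace = best
    design.validate()
    info = mnl_information(design, priors)
    score = DesignScore(d_error=d_error(design, priors), information=info,
                        priors=priors, trace=trace)
    return design, score


def design_diagnostics(design: Design, attrs: AttributeSet | None = None) -> dict:
    """Level balance, within-task attribute overlap, and dominance flags.

    Dominance considers sign-ordered attributes only (expected_sign set):
    a task is flagged when one non-opt-out alternative is weakly better on
    every such attribute and strictly better on at least one.
    """
    attrs = attrs or design.attrs
    freq: dict[str, dict[str, int]] = {
        a.name: {lab: 0 for lab in a.level_labels} for a in attrs.attributes}
    overlap: dict[int, int] = {}
    dominance: dict[int, bool] = {}

    for task in design.tasks:
        assigns = [a for a, oo in task.alternatives if not oo]
        for a in assigns:
            for attr in attrs.attributes:
                freq[attr.name][attr.level_labels[a[attr.name]]] += 1
        overlap[task.task_id] = sum(
            1 for attr in attrs.attributes
            if len({a[attr.name] for a in assigns}) == 1)
        dominance[task.task_id] = _task_dominated(assigns, attrs)

    return {"level_frequencies": freq, "task_overlap": overlap, "task_dominance": dominance}


def _task_dominated(assigns: list[dict[str, int]], attrs: AttributeSet) -> bool:
    signed = [a for a in attrs.attributes if a.expected_sign != "none"]
    if not signed:
        return False
    for i, cand in enumerate(assigns):
        for j, other in enumerate(assigns):
            if i == j:
                continue
            weakly, strictly = True, False
            for attr in signed:
                diff = attr.level_codes[cand[attr.name]] - attr.level_codes[other[attr.name]]
                better = diff if attr.expected_sign == "positive" else -diff
                if better < 0:
                    weakly = False
                    break
                if better > 0:
                    strictly = True
            if weakly and strictly:
                return True
    return False
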