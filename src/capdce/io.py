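"""File formats: long-format choice CSV and design CSV (comma, dot decimal,
UTF-8).  Every written file starts with ``#``-prefixed metadata lines (seed,
config hash, column roles) that readers skip; round-trips are lossless."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .design import ChoiceTask, Design, DesignConfigError
from .schema import AttributeSet
from .simulate import ID_COLUMNS, ChoiceDataset, DataError

__all__ = [
    "write_choice_csv",
    "read_choice_csv",
    "write_design_csv",
    "read_design_csv",
    "ParseError",
    "file_sha256",
]


class ParseError(ValueError):
    pass


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _metadata_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in meta.items())


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# choice data

def write_choice_csv(data: ChoiceDataset, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    meta = dict(meta or {})
    meta.setdefault("format", "capdce-choices-v1")
    meta["params"] = ",".join(data.param_names)
    cols = [c for c in ID_COLUMNS if c in data.table.columns]
    cols += [c for c in data.table.columns if c not in cols]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_header(meta))
        data.table[cols].to_csv(fh, index=False)


def read_choice_csv(path: str | Path) -> ChoiceDataset:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    meta = _read_metadata(path)
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no data rows") from None
    if len(table) == 0:
        raise ParseError(f"{path}: no data rows")
    required = [c for c in ID_COLUMNS if c != "rank"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if "params" in meta:
        params = tuple(p for p in meta["params"].split(",") if p)
    else:
        params = tuple(c for c in table.columns if c not in ID_COLUMNS and c != "unacceptable")
    keys = table[["respondent_id", "task_id", "alt_id"]]
    if keys.duplicated().any():
        rows = (keys.index[keys.duplicated()] + 1).tolist()
        raise ParseError(f"{path}: duplicate (respondent, task, alt) keys at data row(s) {rows}")
    counts = table.groupby(["respondent_id", "task_id"])["chosen"].sum()
    bad = counts[counts != 1]
    if len(bad):
        resp, task = bad.index[0]
        raise ParseError(
            f"{path}: respondent {resp} task {task} has {int(bad.iloc[0])} chosen rows (need exactly 1)")
    try:
        return ChoiceDataset(table=table, param_names=params)
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# designs

def write_design_csv(design: Design, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    attrs = design.attrs
    meta = dict(meta or {})
    meta.setdefault("format", "capdce-design-v1")
    rows = []
    for task in design.tasks:
        for j, (assignment, is_oo) in enumerate(task.alternatives):
            row: dict = {"task_id": task.task_id, "alt_id": j + 1, "is_optout": int(is_oo)}
            for a in attrs.attributes:
                if is_oo:
                    row[f"{a.name}_label"] = ""
                    row[f"{a.name}_code"] = ""
                else:
                    idx = assignment[a.name]
                    row[f"{a.name}_label"] = a.level_labels[idx]
                    row[f"{a.name}_code"] = a.level_codes[idx]
            rows.append(row)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_header(meta))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_design_csv(path: str | Path, attrs: AttributeSet) -> Design:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    table = pd.read_csv(path, comment="#")
    label_to_idx = {a.name: {lab: i for i, lab in enumerate(a.level_labels)}
                    for a in attrs.attributes}
    tasks: list[ChoiceTask] = []
    for task_id, grp in table.groupby("task_id", sort=True):
        alternatives: list[tuple[dict[str, int] | None, bool]] = []
        for _, row in grp.sort_values("alt_id").iterrows():
            if int(row["is_optout"]):
                alternatives.append((None, True))
                continue
            assignment: dict[str, int] = {}
            for a in attrs.attributes:
                label = row[f"{a.name}_label"]
                if label not in label_to_idx[a.name]:
                    raise ParseError(f"{path}: task {task_id}: unknown level {label!r} for {a.name!r}")
                assignment[a.name] = label_to_idx[a.name][label]
            alternatives.append((assignment, False))
        tasks.append(ChoiceTask(task_id=int(task_id), alternatives=alternatives))
    design = Design(tasks=tasks, attrs=attrs)
    try:
        design.validate()
    except DesignConfigError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return design


def result_to_json(res, stats=None, post=None) -> str:
    """Serialize an MNLResult (+ optional FitStats / PostEstimates) to JSON."""
    payload = {
        "param_names": list(res.param_names),
        "beta_hat": [float(b) for b in res.beta_hat],
        "se_robust": [float(s) for s in res.se_robust],
        "se_classical": [float(s) for s in res.se_classical],
        "cov_robust": [[float(v) for v in row] for row in res.cov_robust],
        "cov_classical": [[float(v) for v in row] for row in res.cov_classical],
        "ll_final": res.ll_final,
        "ll_null": res.ll_null,
        "n_obs": res.n_obs,
        "n_respondents": res.n_respondents,
        "K": res.k,
        "converged": res.converged,
        "grad_norm": res.grad_norm,
        "n_dropped_tasks": res.n_dropped_tasks,
    }
    if stats is not None:
        payload["fit_stats"] = {"aic": stats.aic, "bic": stats.bic,
                                "adj_rho2": stats.adj_rho2, "baseline": stats.baseline_used}
    if post is not None:
        payload["wta"] = {k: {"estimate": v[0], "se": v[1]} for k, v in post.wta.items()}
        payload["importance"] = {k: {"max_effect": v[0], "share": v[1]}
                                 for k, v in post.importance.items()}
    return json.dumps(payload, indent=2)
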