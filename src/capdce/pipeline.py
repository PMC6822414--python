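"""End-to-end orchestration: design -> simulate -> fit -> report.

Every stage writes its artifact with the seed and config hash in the file
header; the run manifest records stage outputs, row counts, and content
hashes so that identical configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import optimize_design
from .estimate import fit_mnl, fit_stats
from .io import file_sha256, result_to_json, write_choice_csv, write_design_csv
from .postest import PostEstimationError, post_estimates
from .schema import AttributeSet, load_attribute_config
from .simulate import SimulationConfig, simulate_choices

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    attribute_config: str | Path
    out_dir: str | Path
    n_tasks: int = 8
    n_nonoptout_alts: int = 2
    design_seed: int = 0
    design_starts: int = 5
    priors: list[float] | None = None
    beta_true: list[float] | None = None
    n_respondents: int = 31
    sim_seed: int = 0
    include_optout: bool = True
    cluster: bool = True
    baseline_ll: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    # out_dir is where results land, not what they are — exclude it so the
    # same scientific config hashes identically wherever it is run
    blob = json.dumps(
        {k: (str(v) if isinstance(v, Path) else v) for k, v in vars(cfg).items()
         if k != "out_dir"},
        sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all four stages; returns (and writes) the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    writing a FAILED marker next to whatever partial outputs exist.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    manifest: dict = {"tool": "capdce", "version": __version__,
                      "config_hash": cfg_hash, "stages": {}}
    stage = "load_config"
    try:
        attrs: AttributeSet = load_attribute_config(cfg.attribute_config)

        stage = "design"
        priors = None if cfg.priors is None else np.asarray(cfg.priors, dtype=float)
        design, score = optimize_design(attrs, cfg.n_tasks, cfg.n_nonoptout_alts,
                                        priors=priors, seed=cfg.design_seed,
                                        n_starts=cfg.design_starts)
        design_path = out_dir / "design.csv"
        write_design_csv(design, design_path,
                         meta={"seed": cfg.design_seed, "config_hash": cfg_hash,
                               "d_error": f"{score.d_error:.10g}"})
        logger.info("design: %d tasks x %d alts, d_error=%.6g",
                    design.n_tasks, design.n_alts, score.d_error)
        manifest["stages"]["design"] = {"file": design_path.name, "n_tasks": design.n_tasks,
                                        "d_error": score.d_error,
                                        "sha256": file_sha256(design_path)}

        stage = "simulate"
        beta_true = (np.asarray(cfg.beta_true, dtype=float) if cfg.beta_true is not None
                     else attrs.default_priors())
        sim_cfg = SimulationConfig(beta_true=beta_true, n_respondents=cfg.n_respondents,
                                   seed=cfg.sim_seed)
        data = simulate_choices(design, sim_cfg)
        choices_path = out_dir / "choices.csv"
        write_choice_csv(data, choices_path,
                         meta={"seed": cfg.sim_seed, "config_hash": cfg_hash})
        logger.info("simulate: %d respondents, %d rows, %d observations",
                    data.n_respondents, len(data.table), data.n_obs)
        manifest["stages"]["simulate"] = {"file": choices_path.name,
                                          "n_rows": len(data.table), "n_obs": data.n_obs,
                                          "sha256": file_sha256(choices_path)}

        stage = "fit"
        res = fit_mnl(data, include_optout=cfg.include_optout,
                      cluster_by_respondent=cfg.cluster)
        stats = fit_stats(res, baseline=cfg.baseline_ll)
        logger.info("fit: K=%d, ll=%.4f, converged=%s (dropped %d forced-choice tasks)",
                    res.k, res.ll_final, res.converged, res.n_dropped_tasks)

        stage = "report"
        post = None
        if attrs.cost_attribute is not None:
            try:
                post = post_estimates(res, attrs)
            except PostEstimationError as exc:
                logger.warning("post-estimation skipped: %s", exc)
        fit_path = out_dir / "fit.json"
        header = {"seed": cfg.sim_seed, "config_hash": cfg_hash}
        fit_path.write_text(json.dumps({"meta": header,
                                        **json.loads(result_to_json(res, stats, post))},
                                       indent=2))
        manifest["stages"]["fit"] = {"file": fit_path.name, "n_obs": res.n_obs,
                                     "n_respondents": res.n_respondents,
                                     "converged": res.converged,
                                     "sha256": file_sha256(fit_path)}
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
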