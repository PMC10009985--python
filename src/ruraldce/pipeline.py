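"""End-to-end orchestration: design -> simulate -> fit -> post-estimate.

A run is described by a plain YAML config (see :class:`RunConfig`); one
master seed is expanded into per-stage child seeds by a fixed rule
(`numpy.random.SeedSequence(seed).generate_state`, stage order design,
simulate, fit, postestimation), so any stage can be reproduced in
isolation.  Every run writes a JSON manifest listing all artifacts, the
seeds used and stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import AttributeSchema, ChoiceDataset, default_schema, read_choice_csv
from .design import PairedDesign, assign_blocks, build_paired_design, diagnose_design
from .estimation import fit_clogit, fit_lcm, fit_mixl, select_classes
from .postestimation import relative_importance, uptake_table, wta_table
from .simulate import (
    DataGeneratingProcess,
    reference_clogit_dgp,
    reference_lcm_dgp,
    reference_mixl_dgp,
    simulate_choices,
    draw_preferences,
    make_covariates,
    spawn_seeds,
)

log = logging.getLogger("ruraldce")

STAGES = ("design", "simulate", "fit", "postestimation")

DGP_PRESETS = {
    "clogit": reference_clogit_dgp,
    "mixl": reference_mixl_dgp,
    "latent_class": reference_lcm_dgp,
}


class PipelineError(RuntimeError):
    """A stage failed or a required upstream artifact is missing."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: Path
    seed: int = 0
    schema_path: Path | None = None
    stages: tuple = STAGES
    design: dict = field(default_factory=dict)  # n_tasks, n_blocks, n_iter
    simulate: dict = field(default_factory=dict)  # dgp preset, n_respondents
    data_path: Path | None = None  # alternative to the simulate stage
    fit: dict = field(default_factory=lambda: {"clogit": True})
    postestimation: dict = field(default_factory=dict)  # wta/importance/uptake

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(
            outdir=Path(doc.get("outdir", "dce_run")),
            seed=int(doc.get("seed", 0)),
            schema_path=Path(doc["schema"]) if doc.get("schema") else None,
            stages=tuple(doc.get("stages", STAGES)),
            design=doc.get("design", {}) or {},
            simulate=doc.get("simulate", {}) or {},
            data_path=Path(doc["data"]) if doc.get("data") else None,
            fit=doc.get("fit", {"clogit": True}) or {},
            postestimation=doc.get("postestimation", {}) or {},
        )
        if cfg.schema_path and not cfg.schema_path.exists():
            raise PipelineError("config", f"schema file {cfg.schema_path} does not exist")
        if cfg.data_path and not cfg.data_path.exists():
            raise PipelineError("config", f"data file {cfg.data_path} does not exist")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, spawn_seeds(config.seed, len(STAGES))))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "artifacts": {},
        "timings_s": {},
    }
    schema = (
        AttributeSchema.from_yaml(config.schema_path)
        if config.schema_path
        else default_schema()
    )
    schema_file = outdir / "schema.yaml"
    schema.to_yaml(schema_file)
    manifest["artifacts"]["schema"] = str(schema_file)

    design = None
    dataset = None
    fits = {}
    for stage in config.stages:
        if stage not in STAGES:
            raise PipelineError(stage, "unknown stage")
        t0 = time.perf_counter()
        log.info("stage %s (seed %d)", stage, seeds[stage])
        if stage == "design":
            design = _run_design(config, schema, seeds[stage], outdir, manifest)
        elif stage == "simulate":
            design, dataset = _run_simulate(
                config, schema, design, seeds[stage], outdir, manifest
            )
        elif stage == "fit":
            dataset = _require_data(config, schema, dataset)
            fits = _run_fit(config, schema, dataset, seeds[stage], outdir, manifest)
        elif stage == "postestimation":
            _run_postestimation(config, schema, fits, seeds[stage], outdir, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    manifest_file = outdir / "manifest.json"
    with open(manifest_file, "w") as fh:
        json.dump(manifest, fh, indent=2)
    missing = [p for p in manifest["artifacts"].values() if not Path(p).exists()]
    if missing:
        raise PipelineError("manifest", f"listed artifacts missing on disk: {missing}")
    return manifest


def _run_design(config, schema, seed, outdir, manifest):
    opts = dict(config.design)
    design, diag = build_paired_design(
        schema,
        n_tasks=int(opts.get("n_tasks", 24)),
        n_blocks=int(opts.get("n_blocks", 3)),
        seed=seed,
        n_iter=int(opts.get("n_iter", 4000)),
    )
    path = outdir / "design.csv"
    design.to_csv(path, schema)
    manifest["artifacts"]["design"] = str(path)
    diag_path = outdir / "design_diagnostics.json"
    with open(diag_path, "w") as fh:
        json.dump(
            {
                "orthogonality": diag.orthogonality,
                "mean_overlap": diag.mean_overlap,
                "max_utility_imbalance": diag.max_utility_imbalance,
                "level_balance": diag.level_balance,
            },
            fh,
            indent=2,
        )
    manifest["artifacts"]["design_diagnostics"] = str(diag_path)
    return design


def _run_simulate(config, schema, design, seed, outdir, manifest):
    if design is None:
        design_path = config.design.get("path")
        if not design_path:
            raise PipelineError("simulate", "missing upstream artifact: design")
        design = PairedDesign.from_csv(design_path, schema)
    opts = dict(config.simulate)
    preset = opts.get("dgp", "mixl")
    if preset not in DGP_PRESETS:
        raise PipelineError("simulate", f"unknown DGP preset {preset!r}")
    dgp = DGP_PRESETS[preset]()
    n = int(opts.get("n_respondents", 352))
    s_cov, s_pref, s_blocks, s_noise = spawn_seeds(seed, 4)
    covariates = make_covariates(n, seed=s_cov)
    betas, _ = draw_preferences(dgp, n, seed=s_pref, covariates=covariates)
    assignment = assign_blocks(design, n, design.blocks_per_respondent, seed=s_blocks)
    dataset = simulate_choices(
        design, schema, assignment, betas, seed=s_noise, covariates=covariates
    )
    path = outdir / "dataset.csv"
    dataset.to_csv(path)
    manifest["artifacts"]["dataset"] = str(path)
    manifest["n_observations"] = dataset.n_observations
    return design, dataset


def _require_data(config, schema, dataset):
    if dataset is not None:
        return dataset
    if config.data_path is None:
        raise PipelineError("fit", "missing upstream artifact: dataset")
    return read_choice_csv(config.data_path, schema)


def _run_fit(config, schema, dataset, seed, outdir, manifest):
    fits = {}
    opts = config.fit
    if opts.get("clogit"):
        res = fit_clogit(dataset, schema)
        path = outdir / "fit_clogit.csv"
        res.summary().to_csv(path)
        manifest["artifacts"]["fit_clogit"] = str(path)
        fits["clogit"] = res
    if opts.get("mixl"):
        mopts = opts["mixl"] if isinstance(opts["mixl"], dict) else {}
        res = fit_mixl(
            dataset, schema, R=int(mopts.get("R", 2000)), seed=seed,
            maxiter=int(mopts.get("maxiter", 300)),
        )
        path = outdir / "fit_mixl.csv"
        res.summary().to_csv(path)
        manifest["artifacts"]["fit_mixl"] = str(path)
        fits["mixl"] = res
    if opts.get("lcm"):
        lopts = opts["lcm"] if isinstance(opts["lcm"], dict) else {}
        C_range = lopts.get("C_range")
        if C_range:
            table, chosen, all_fits = select_classes(
                dataset, schema, C_range=C_range, seed=seed,
                n_starts=int(lopts.get("n_starts", 3)),
            )
            table.to_csv(outdir / "lcm_selection.csv", index=False)
            manifest["artifacts"]["lcm_selection"] = str(outdir / "lcm_selection.csv")
            manifest["lcm_chosen_C"] = chosen
            res = all_fits[chosen]
        else:
            res = fit_lcm(
                dataset, schema, C=int(lopts.get("C", 3)), seed=seed,
                n_starts=int(lopts.get("n_starts", 3)),
            )
        path = outdir / "fit_lcm.csv"
        out = res.class_coefs.copy()
        out.loc["share"] = res.shares
        out.to_csv(path)
        manifest["artifacts"]["fit_lcm"] = str(path)
        fits["lcm"] = res
    if not fits:
        raise PipelineError("fit", "no estimator requested in config")
    return fits


def _run_postestimation(config, schema, fits, seed, outdir, manifest):
    opts = config.postestimation or {"wta": True, "importance": True, "uptake": True}
    mixl = fits.get("mixl") or fits.get("clogit")
    if opts.get("wta") or opts.get("uptake"):
        if mixl is None:
            raise PipelineError("postestimation", "missing upstream artifact: mixl fit")
    if opts.get("wta"):
        # clogit results carry full covariance too; ratio code only needs means+cov
        res = _as_ratio_result(mixl)
        table = wta_table(res, seed=seed)
        path = outdir / "wta.csv"
        table.to_csv(path, index=False)
        manifest["artifacts"]["wta"] = str(path)
    if opts.get("importance"):
        lcm = fits.get("lcm")
        if lcm is None:
            raise PipelineError("postestimation", "missing upstream artifact: lcm fit")
        imp = relative_importance(lcm, schema)
        path = outdir / "relative_importance.csv"
        out = imp.scores.copy()
        out["pooled"] = imp.pooled
        out.to_csv(path)
        manifest["artifacts"]["relative_importance"] = str(path)
    if opts.get("uptake"):
        res = _as_ratio_result(mixl)
        table = uptake_table(res, schema, seed=seed)
        path = outdir / "uptake.csv"
        table.to_csv(path, index=False)
        manifest["artifacts"]["uptake"] = str(path)


def _as_ratio_result(fit):
    """Adapt a conditional logit result to the means+cov interface."""
    from .estimation import CLogitResult, MIXLResult

    if isinstance(fit, MIXLResult):
        return fit
    if isinstance(fit, CLogitResult):
        return MIXLResult(
            means=fit.coefficients,
            sds=pd.Series(dtype=float),
            se_means=fit.se,
            se_sds=pd.Series(dtype=float),
            cov=fit.cov,
            loglik=fit.loglik,
            n_draws=0,
            draw_type="none",
            random=(),
            n_observations=fit.n_observations,
            converged=fit.converged,
        )
    raise TypeError(f"cannot adapt {type(fit).__name__}")
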