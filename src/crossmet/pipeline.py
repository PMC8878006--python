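"""End-to-end orchestration of the crossover metabolomics analysis.

``run_pipeline`` chains: simulate (or load) -> QC-RLSC -> PPCA imputation
-> quotient normalization -> log transform/centering -> multilevel
variance removal -> sPLS-DA tuning and fit -> candidate selection with
FDR validation and fold changes -> formula annotation.  Every stage
writes its output (CSV for tables, JSON for models and reports) into a
run directory, so any stage can be re-run from the previous stage's
files, and a rerun with the same config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design_io, preprocess, selection as selection_mod, splsda as splsda_mod
from .annotation import annotate_feature, load_candidates_csv
from .design_io import FeatureTable, StudyDesign
from .multilevel import MultilevelSPLSDA
from .synthetic import SyntheticSpec, simulate_study

log = logging.getLogger("crossmet")


@dataclass
class PipelineConfig:
    """Everything one run needs; seed is mandatory for reproducibility."""

    seed: int
    out_dir: str = "crossmet_run"
    # inputs: either synthetic (default) or paths to feature table + design
    feature_table: str | None = None
    design: str | None = None
    synthetic: dict = field(default_factory=dict)
    # preprocessing
    qc_span: float = 0.75
    ppca_components: int = 3
    transform: str = "log10"
    scaling: str = "none"
    # multilevel + sPLS-DA
    discriminant: tuple = ("phase",)
    subtract: str = "subject"
    n_components: int = 2
    keepx_grid: tuple = (50, 60, 70)
    n_folds: int = 7
    n_repeats: int = 3
    tune_criterion: str = "error"
    run_tuning: bool = True
    # selection + annotation
    selection: dict = field(default_factory=dict)
    candidates: str | None = None
    annotation_tol_ppm: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            t0 = time.time()
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage=%s wall_time=%.2fs", name, time.time() - t0)
            return out
        return inner
    return wrap


@_stage("simulate")
def _acquire(cfg: PipelineConfig, out: Path):
    if cfg.feature_table and cfg.design:
        table = design_io.load_feature_table(cfg.feature_table)
        design = design_io.load_design(cfg.design)
        truth = None
    else:
        spec = SyntheticSpec(**{"seed": cfg.seed, "missing_rate": 0.05,
                                "drift_slope": 0.002, **cfg.synthetic})
        table, design, truth = simulate_study(spec)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({
                "affected_feature_ids": truth.affected_feature_ids,
                "effect_directions": {
                    f: d for f, d in truth.effect_directions.items() if d
                },
                "spec": dataclasses.asdict(spec),
            }, fh, indent=2)
    design_io.write_feature_table(table, out / "01_raw_table.csv")
    design_io.write_design(design, out / "01_design.csv")
    return table, design, truth


@_stage("preprocess")
def _preprocess(cfg: PipelineConfig, table, design, out: Path):
    if design.samples["is_qc"].sum() >= 4:
        table = preprocess.qc_rlsc(table, design, span=cfg.qc_span)
    if np.isnan(table.values).any():
        # impute on the log scale so imputed intensities stay positive
        log_table = table.with_values(np.log(table.values), raw=False)
        imputed = preprocess.impute_ppca(log_table,
                                         n_components=cfg.ppca_components,
                                         seed=cfg.seed)
        table = table.with_values(np.exp(imputed.values), raw=True)
    study_ids = design.non_qc.index
    table = table.subset_samples(study_ids)
    design = design.subset(study_ids)
    control = design.samples.index[design.samples["phase"].isin(["baseline", "placebo"])]
    table = preprocess.normalize_reference(table, control)
    design_io.write_feature_table(table, out / "02_preprocessed.csv")
    scaled = preprocess.transform_scale(table, cfg.transform, cfg.scaling)
    design_io.write_feature_table(scaled, out / "03_transformed.csv")
    return table, scaled, design


@_stage("fit")
def _fit(cfg: PipelineConfig, scaled, design, out: Path):
    keepx = None
    tune_payload = None
    ml = MultilevelSPLSDA(scaled, design, cfg.discriminant, cfg.subtract,
                          n_components=cfg.n_components)
    if cfg.run_tuning:
        labels = ml.class_series.to_numpy()
        from .multilevel import remove_variation
        resid = remove_variation(ml.X, ml.grouping).residual
        tuned = splsda_mod.tune(
            resid, labels, keepx_grid=cfg.keepx_grid,
            n_components=cfg.n_components, n_folds=cfg.n_folds,
            n_repeats=cfg.n_repeats, criterion=cfg.tune_criterion,
            seed=cfg.seed,
        )
        keepx = tuned.chosen_keepx
        tune_payload = {
            "grid": list(tuned.keepx_grid),
            "errors": tuned.errors.tolist(),
            "correlations": tuned.correlations.tolist(),
            "chosen_keepx": list(map(int, keepx)),
        }
        with open(out / "04_tuning.json", "w") as fh:
            json.dump(tune_payload, fh, indent=2)
    ml = MultilevelSPLSDA(scaled, design, cfg.discriminant, cfg.subtract,
                          n_components=cfg.n_components, keepx=keepx)
    res = ml.fit()
    with open(out / "05_model.json", "w") as fh:
        json.dump(res.to_json(), fh, indent=2)
    res.splsda.to_json(out / "05_model_weights.json")
    res.scores_frame().to_csv(out / "05_scores.csv")
    perf = splsda_mod.performance(
        res.decomposition.residual, ml.class_series.to_numpy(),
        n_components=cfg.n_components, keepx=res.splsda.keepx,
        n_folds=cfg.n_folds, seed=cfg.seed,
    )
    with open(out / "06_performance.json", "w") as fh:
        json.dump({
            "r2": perf.r2.tolist(), "q2": perf.q2.tolist(),
            "error_rate": perf.error_rate,
            "balanced_error_rate": perf.balanced_error_rate,
        }, fh, indent=2)
    return res, perf, tune_payload


@_stage("select")
def _select(cfg: PipelineConfig, table, design, res, out: Path):
    sel_cfg = selection_mod.SelectionConfig(**cfg.selection)
    report = selection_mod.selection_report(
        table, design, res.splsda, res.decomposition.residual, sel_cfg)
    report.to_csv(out / "07_selection.csv")
    return report


@_stage("annotate")
def _annotate(cfg: PipelineConfig, table, report, out: Path):
    if not cfg.candidates:
        return None
    candidates = load_candidates_csv(cfg.candidates)
    rows = []
    for feat in report.index:
        mz = float(table.feature_meta.loc[feat, "mz"])
        pol = str(table.feature_meta.loc[feat, "polarity"])
        for rec in annotate_feature(mz, pol, candidates, cfg.annotation_tol_ppm):
            row = {"feature": feat, **rec.as_row()}
            rows.append(row)
    ann = pd.DataFrame(rows)
    ann.to_csv(out / "08_annotation.csv", index=False)
    return ann


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run start seed=%d", config.seed)
        table, design, truth = _acquire(config, out)
        table, scaled, design = _preprocess(config, table, design, out)
        res, perf, tuned = _fit(config, scaled, design, out)
        report = _select(config, table, design, res, out)
        ann = _annotate(config, table, report, out)
        summary = {
            "seed": config.seed,
            "n_samples": int(table.n_samples),
            "n_features": int(table.n_features),
            "discriminant": list(config.discriminant),
            "subtract": config.subtract,
            "keepx": list(map(int, res.splsda.keepx)),
            "error_rate": perf.error_rate,
            "balanced_error_rate": perf.balanced_error_rate,
            "r2": perf.r2.tolist(),
            "q2": perf.q2.tolist(),
            "n_selected": int(len(report)),
            "n_significant": int(report["significant"].sum()),
            "n_annotated": int(len(ann)) if ann is not None else 0,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
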