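"""End-to-end orchestration: simulate -> qc -> dep -> select -> validate.

A run is configured by a :class:`RunConfig` (optionally loaded from YAML),
executes the stages in order into an output directory, and records a
manifest with per-stage outputs, SHA-256 checksums, timings and warnings.
Identical config + seed reproduces identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .differential import call_deps, embed_umap
from .ihc import (
    add_hscore,
    auc_delong,
    correlation_cluster,
    logistic_combination,
    positivity_tests,
    rank_sum_test,
)
from .qc import compute_cvs, impute_missing, tukey_fence_impute
from .select import RFConfig, consensus, select_lasso, select_rf, select_svm
from .simulate import GROUP_A, GROUP_B, SimulationConfig, simulate_abundance, simulate_ihc

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

STAGES = ("simulate", "qc", "dep", "select", "validate")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``matrix_path``/``sheet_path`` are unset, inputs are generated by
    the synthetic-data stage from ``simulation``.  Numeric defaults follow
    the study-design conventions: Tukey k = 2, missing fill 0.8 x min,
    alpha 0.05, |log2FC| > 0.25, MDA > 3 with 1000 trees and 50 stratified
    4:1 hold-outs, 10-fold 1-SE LASSO, consensus at 2 votes.
    """

    out_dir: str = "panelforge_run"
    seed: int = 0
    matrix_path: str | None = None
    sheet_path: str | None = None
    hscore_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tukey_k: float = 2.0
    impute_factor: float = 0.8
    alpha: float = 0.05
    lfc: float = 0.25
    rf: RFConfig = field(default_factory=RFConfig)
    min_votes: int = 2
    svm_iterations: int = 6
    lasso_folds: int = 10
    umap: bool = True
    ihc_n_a: int = 11
    ihc_n_b: int = 19
    ihc_auc_target: float = 0.9
    positivity_cutoff: float = 100.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        rf = RFConfig(**raw.pop("rf", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, rf=rf, **raw)


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "stages": self.stages, "warnings": self.warnings},
                fh,
                indent=1,
                default=str,
            )


def _stage_record(name: str, outputs: list[Path], t0: float) -> dict:
    return {
        "stage": name,
        "outputs": {p.name: io.sha256sum(p) for p in outputs},
        "seconds": round(time.perf_counter() - t0, 3),
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order; halts with a stage-named diagnostic."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(config=dataclasses.asdict(config))

    # ---- simulate (or load) -------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.matrix_path and config.sheet_path:
            matrix = io.read_matrix(config.matrix_path)
            sheet = io.read_sheet(config.sheet_path)
            truth = None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            matrix, sheet, truth = simulate_abundance(sim)
        missing = set(sheet.sample_id) - set(matrix.columns)
        if missing:
            raise ValueError(f"sheet samples absent from matrix: {sorted(missing)}")
        io.write_matrix(matrix, out / "matrix.tsv")
        io.write_sheet(sheet, out / "sample_sheet.csv")
        outputs = [out / "matrix.tsv", out / "sample_sheet.csv"]
        if truth is not None:
            truth.to_json(out / "ground_truth.json")
            outputs.append(out / "ground_truth.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    manifest.stages.append(_stage_record("simulate", outputs, t0))

    # ---- qc ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        matrix_qc, fence = tukey_fence_impute(matrix, k=config.tukey_k)
        qc_report = compute_cvs(matrix_qc, sheet)
        qc_report.fence = fence
        io.write_matrix(matrix_qc, out / "matrix_qc.tsv")
        qc_report.to_json(out / "qc_report.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
    manifest.stages.append(
        _stage_record("qc", [out / "matrix_qc.tsv", out / "qc_report.json"], t0)
    )
    if not qc_report.pool_pass:
        manifest.warnings.append("median pool CV exceeds the 20% threshold")

    # ---- dep -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        deps = call_deps(matrix_qc, sheet, alpha=config.alpha, lfc=config.lfc)
        deps.to_csv(out / "dep_table.tsv", sep="\t", float_format="%.6g")
        outputs = [out / "dep_table.tsv"]
        dep_ids = deps.index[deps.is_dep]
        study_cols = sheet.loc[sheet.role == "study", "sample_id"].tolist()
        if config.umap and len(dep_ids) > 0 and len(study_cols) >= 3:
            coords = embed_umap(matrix_qc.loc[dep_ids, study_cols], seed=config.seed)
            coords.to_csv(out / "umap.csv")
            outputs.append(out / "umap.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'dep' failed: {exc}") from exc
    manifest.stages.append(_stage_record("dep", outputs, t0))

    # ---- select --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        study = sheet[sheet.role == "study"]
        study_cols = study.sample_id.tolist()
        labels = study.group.to_numpy()
        imputed = impute_missing(matrix_qc[study_cols], factor=config.impute_factor)
        io.write_matrix(imputed, out / "matrix_imputed.tsv")

        dep_ids = deps.index[deps.is_dep]
        sets = []
        rf_cfg = dataclasses.replace(config.rf, seed=int(rng.integers(2**31 - 1)))
        if len(dep_ids) > 0:
            sets.append(select_rf(imputed.loc[dep_ids], labels, rf_cfg))
        else:
            manifest.warnings.append("empty DEP set: random-forest selector skipped")
        sets.append(
            select_lasso(
                imputed, labels, n_folds=config.lasso_folds,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        sets.append(
            select_svm(
                imputed, labels, n_iterations=config.svm_iterations,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        panel = consensus(sets, min_votes=config.min_votes, dep_table=deps)
        outputs = [out / "matrix_imputed.tsv"]
        for fs in sets:
            fs.members.to_csv(out / f"features_{fs.algorithm}.tsv", sep="\t", index=False)
            outputs.append(out / f"features_{fs.algorithm}.tsv")
        panel.members.to_csv(out / "consensus_panel.tsv", sep="\t", index=False)
        outputs.append(out / "consensus_panel.tsv")
        select_meta = {
            "rf_retained_models": next(
                (fs.metadata["retained_models"] for fs in sets if fs.algorithm == "rf"), None
            ),
            "lasso_lambda_1se": next(
                (fs.metadata["lambda_1se"] for fs in sets if fs.algorithm == "lasso"), None
            ),
            "svm_k_star": next(
                (fs.metadata["k_star"] for fs in sets if fs.algorithm == "svm"), None
            ),
            "set_sizes": {fs.algorithm: len(fs) for fs in sets},
            "panel_size": len(panel),
        }
        with open(out / "select_manifest.json", "w") as fh:
            json.dump(select_meta, fh, indent=1)
        outputs.append(out / "select_manifest.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'select' failed: {exc}") from exc
    manifest.stages.append(_stage_record("select", outputs, t0))

    # ---- validate ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.hscore_path:
            hscores = add_hscore(io.read_hscores(config.hscore_path))
        else:
            markers = panel.proteins[:5] or ["M1", "M2", "M3"]
            directions = {}
            for _, row in panel.members.iterrows():
                directions[row.protein] = 1 if row.direction == f"up_in_{GROUP_A}" else -1
            hscores = simulate_ihc(
                config.ihc_n_a,
                config.ihc_n_b,
                markers,
                {m: config.ihc_auc_target for m in markers},
                seed=int(rng.integers(2**31 - 1)),
                directions=directions,
            )
        io.write_hscores(hscores, out / "hscores.csv")
        wide = hscores.pivot(index="patient_id", columns="marker", values="hscore")
        groups = hscores.drop_duplicates("patient_id").set_index("patient_id")["group"]
        groups = groups.loc[wide.index]

        rows, contingency = [], {}
        for m in wide.columns:
            roc = auc_delong(wide[m], groups, marker=m, positive_label=GROUP_A)
            u, p_rank = rank_sum_test(
                wide.loc[groups == GROUP_A, m], wide.loc[groups == GROUP_B, m]
            )
            pos = wide[m] > config.positivity_cutoff
            table = [
                [int((pos & (groups == GROUP_A)).sum()), int((pos & (groups == GROUP_B)).sum())],
                [int((~pos & (groups == GROUP_A)).sum()), int((~pos & (groups == GROUP_B)).sum())],
            ]
            contingency[m] = positivity_tests(table) | {"table": table}
            rows.append(
                {
                    "marker": m,
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "delong_p": roc.p_value,
                    "direction": roc.direction,
                    "rank_sum_p": p_rank,
                }
            )
        roc_table = pd.DataFrame(rows)
        roc_table.to_csv(out / "roc_summary.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out / "contingency.json", "w") as fh:
            json.dump(contingency, fh, indent=1)

        coef, combo_roc, separated = logistic_combination(wide, groups, positive_label=GROUP_A)
        cluster = correlation_cluster(wide, labels=groups)
        with open(out / "validation_summary.json", "w") as fh:
            json.dump(
                {
                    "combined_auc": combo_roc.auc,
                    "combined_ci": [combo_roc.ci_low, combo_roc.ci_high],
                    "separated": separated,
                    "cluster_agreement": cluster.agreement,
                },
                fh,
                indent=1,
            )
        outputs = [
            out / "hscores.csv",
            out / "roc_summary.tsv",
            out / "contingency.json",
            out / "validation_summary.json",
        ]
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc
    manifest.stages.append(_stage_record("validate", outputs, t0))

    manifest.to_json(out / "run_manifest.json")
    return manifest
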