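"""End-to-end orchestration: ingest/simulate -> preprocess -> fuse -> classify.

`run_full_pipeline` executes the whole diagnostic analysis for plasma-only,
saliva-only and fused cohorts in every available state and returns a
machine-readable :class:`RunReport` (a pydantic model, validated against
the shipped JSON schema on every run). All randomness is routed through a
single seed.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .discriminant import (
    CandidateSpec,
    evaluate_candidate,
    roc_auc,
    search_candidates,
    select_best,
)
from .fusion import FusionError, build_fused_cohort
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spectra import Cohort, load_cohort
from .synthetic import SyntheticConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "GroupResult",
    "RunReport",
    "run_full_pipeline",
    "report_schema",
    "validate_report",
]


class Metrics(BaseModel):
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float


class GroupResult(BaseModel):
    """Selected model + metrics for one (biofluid, state) analysis group."""

    biofluid: str
    state: str
    n_patients: int
    flavor: str
    pc_subset: str
    cv: Metrics
    resubstitution: Metrics
    cv_auc: float


class StageCounts(BaseModel):
    spectra_loaded: int
    spectra_dropped: int
    spectra_kept: int
    patients: int
    fused: dict[str, int] = Field(default_factory=dict)  # state -> n fused


class RunReport(BaseModel):
    version: str
    seed: Optional[int] = None
    config: dict[str, Any]
    counts: StageCounts
    results: list[GroupResult]
    skipped: list[str] = Field(default_factory=list)
    output_files: list[str] = Field(default_factory=list)


class PipelineConfig(BaseModel):
    """Run configuration; either simulate a cohort or load one from disk."""

    simulate: bool = True
    seed: int = 0
    manifest: Optional[str] = None
    data_dir: Optional[str] = None
    states: list[str] = ["dried"]
    n_cancer: int = 34
    n_control: int = 19
    spots_per_sample: int = 5
    spike_rate: float = 0.02
    peak_delta: float = 0.10
    n_pcs: int = 5
    scheme: str = "leave_one_patient_out"
    preprocess: dict[str, Any] = Field(default_factory=dict)


def _metrics(ct) -> Metrics:
    return Metrics(
        tp=ct.tp, fp=ct.fp, tn=ct.tn, fn=ct.fn,
        sensitivity=ct.sensitivity, specificity=ct.specificity, accuracy=ct.accuracy,
    )


def _obtain_cohort(cfg: PipelineConfig) -> Cohort:
    if cfg.simulate:
        scfg = SyntheticConfig(
            n_cancer=cfg.n_cancer,
            n_control=cfg.n_control,
            spots_per_sample=cfg.spots_per_sample,
            states=tuple(cfg.states),
            spike_rate=cfg.spike_rate,
            peak_delta=cfg.peak_delta,
            seed=cfg.seed,
        )
        cohort, _ = simulate_cohort(scfg)
        return cohort
    if not cfg.manifest:
        raise ValueError("either simulate=True or a manifest path is required")
    return load_cohort(cfg.manifest, cfg.data_dir)


def classify_group(
    cohort: Cohort,
    biofluid: str,
    state: str,
    n_pcs: int = 5,
    scheme: str = "leave_one_patient_out",
) -> tuple[GroupResult, pd.DataFrame]:
    """Exhaustive candidate search for one analysis group.

    Returns the GroupResult (CV-selected model with CV + resubstitution
    metrics and CV ROC AUC) and the full CV candidate table.
    """
    X, pids, labels, _ = cohort.to_matrix(biofluid, state)
    cv_table = search_candidates(X, labels, K=n_pcs, scheme=scheme)
    best = select_best(cv_table)
    spec = CandidateSpec(
        flavor=str(best["flavor"]),
        pc_subset=tuple(int(i) for i in str(best["pc_subset"]).split(",")),
    )
    cv_ct, cv_scores, y = evaluate_candidate(X, labels, spec, scheme, n_pcs)
    resub_ct, _, _ = evaluate_candidate(X, labels, spec, "resubstitution", n_pcs)
    roc = roc_auc(cv_scores, y)
    result = GroupResult(
        biofluid=biofluid,
        state=state,
        n_patients=len(pids),
        flavor=spec.flavor,
        pc_subset=",".join(map(str, spec.pc_subset)),
        cv=_metrics(cv_ct),
        resubstitution=_metrics(resub_ct),
        cv_auc=roc.auc,
    )
    return result, cv_table


def run_full_pipeline(
    cfg: PipelineConfig, out_dir: str | Path | None = None
) -> RunReport:
    """Execute the full analysis and emit a validated RunReport.

    Stages: obtain cohort (simulate or load) -> preprocess (crop, despike,
    baseline, smooth, normalize, spot-average) -> per-state classification
    of plasma, saliva, and the fused plasma+saliva cohort. Groups that
    cannot be built (e.g. a fluid absent for every patient) are skipped
    with a recorded reason. When ``out_dir`` is given, candidate tables,
    the despike report and the run report are written there.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    raw = _obtain_cohort(cfg)
    pp_cfg = PreprocessConfig(**cfg.preprocess)
    mean_cohort, despike = preprocess_pipeline(raw, pp_cfg)

    results: list[GroupResult] = []
    skipped: list[str] = []
    files: list[str] = []
    fused_counts: dict[str, int] = {}
    for state in cfg.states:
        for fluid in ("plasma", "saliva"):
            try:
                res, table = classify_group(mean_cohort, fluid, state, cfg.n_pcs, cfg.scheme)
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                skipped.append(f"{fluid}/{state}: {exc}")
                continue
            results.append(res)
            if out_dir:
                fp = out_dir / f"candidates_{fluid}_{state}.csv"
                table.to_csv(fp, index=False)
                files.append(str(fp))
        try:
            fused = build_fused_cohort(mean_cohort, state)
            fused_counts[state] = len(fused)
            res, table = classify_group(fused, "fused", state, cfg.n_pcs, cfg.scheme)
            results.append(res)
            if out_dir:
                fp = out_dir / f"candidates_fused_{state}.csv"
                table.to_csv(fp, index=False)
                files.append(str(fp))
        except (FusionError, Exception) as exc:  # noqa: BLE001
            skipped.append(f"fused/{state}: {exc}")

    counts = StageCounts(
        spectra_loaded=len(raw),
        spectra_dropped=despike.n_flagged,
        spectra_kept=len(raw) - despike.n_flagged,
        patients=len(mean_cohort.patients),
        fused=fused_counts,
    )
    report = RunReport(
        version=__version__,
        seed=cfg.seed if cfg.simulate else None,
        config=cfg.model_dump(),
        counts=counts,
        results=results,
        skipped=skipped,
        output_files=files,
    )
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        despike.to_frame().to_csv(out_dir / "despike_report.csv", index=False)
        report.output_files.append(str(out_dir / "despike_report.csv"))
        (out_dir / "run_report.json").write_text(report.model_dump_json(indent=2))
        report.output_files.append(str(out_dir / "run_report.json"))
    validate_report(json.loads(report.model_dump_json()))
    return report


def report_schema() -> dict:
    """The JSON schema of :class:`RunReport` (also shipped as a data file)."""
    return RunReport.model_json_schema()


def validate_report(obj: dict) -> RunReport:
    """Validate a report dict against the schema; raises on mismatch."""
    shipped = json.loads(
        resources.files("ramanfuse.data").joinpath("run_report_schema.json").read_text()
    )
    if shipped != report_schema():
        raise ValueError("shipped run-report schema is stale; regenerate it")
    return RunReport.model_validate(obj)
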