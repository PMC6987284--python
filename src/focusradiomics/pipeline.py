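"""Configuration-driven orchestration: simulate -> (register) -> extract ->
twist -> classify -> evaluate.

Every stage persists its artefacts (NIfTI volumes, CSV tables, JSON
reports) so a run doubles as an audit trail, and all randomness fans out
deterministically from one global seed: each stage derives its own seed by
stable hashing of the stage name, so adding or toggling a stage never
perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .diagnostics import DiagnosticReport, crossed_evaluation
from .features import extract_cohort
from .registration import RegistrationConfig, register_series
from .synthetic import CohortConfig, KineticParams
from .twist import TwistConfig, TwistResult, evolve, split_balance_report

log = logging.getLogger("focusradiomics")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = zlib.crc32(stage.encode("utf-8"))
    return (int(global_seed) * 2654435761 + h) % (2 ** 31)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    registration_enabled: bool = False     # synthetic default is motion-free
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    n_levels: int = 32
    margin: int = 2
    twist: TwistConfig = field(default_factory=TwistConfig)
    k: int = 3
    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the global seed fans out to the stages
        self.cohort.seed = derive_seed(self.seed, "simulate")
        self.twist.seed = derive_seed(self.seed, "twist")
        self.twist.k = self.k


def _kinetics_from_dict(d: dict) -> dict:
    return {cls: KineticParams(**params) for cls, params in d.items()}


def config_from_yaml(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("volume_shape", "voxel_spacing"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    if "kinetics" in cohort_raw:
        cohort_raw["kinetics"] = _kinetics_from_dict(cohort_raw["kinetics"])
    cfg = PipelineConfig(
        cohort=CohortConfig(**cohort_raw),
        registration_enabled=bool(raw.get("registration_enabled", False)),
        registration=RegistrationConfig(**raw.get("registration", {})),
        n_levels=int(raw.get("n_levels", 32)),
        margin=int(raw.get("margin", 2)),
        twist=TwistConfig(**raw.get("twist", {})),
        k=int(raw.get("k", 3)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "run")),
        log_level=str(raw.get("log_level", "INFO")),
    )
    return cfg


# ---------------------------------------------------------------------------
# stages (each callable on its own; the CLI wraps these 1:1)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> list:
    cases = synthetic.generate_cohort(cfg.cohort)
    synthetic.save_cohort(cases, out_dir / "cases")
    log.info("simulate: %d cases written to %s", len(cases), out_dir / "cases")
    return cases


def stage_register(cases: list, cfg: PipelineConfig, out_dir: Path) -> list:
    reg_dir = out_dir / "registered"
    registered = []
    all_tf = {}
    for case in cases:
        series, transforms = register_series(case.series, cfg.registration)
        registered.append(synthetic.SyntheticCase(
            series, case.mask, case.label, case.truth, case.case_id))
        all_tf[case.case_id] = [[a.to_dict() for a in per_t]
                                for per_t in transforms]
    synthetic.save_cohort(registered, reg_dir)
    (reg_dir / "transforms.json").write_text(
        json.dumps(all_tf, indent=1, sort_keys=True))
    log.info("register: %d cases re-registered", len(registered))
    return registered


def stage_extract(cases: list, cfg: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    table = extract_cohort(cases, n_levels=cfg.n_levels, margin=cfg.margin)
    table.to_csv(out_dir / "features.csv")
    log.info("extract: feature table %s written", table.shape)
    return table


def stage_twist(table: pd.DataFrame, cfg: PipelineConfig,
                out_dir: Path) -> TwistResult:
    result = evolve(table, cfg.twist)
    result.save(out_dir / "twist_result.json")
    balance = split_balance_report(result, table)
    balance.to_csv(out_dir / "balance_report.csv", index=False)
    log.info("twist: %d features selected, best fitness %.3f",
             len(result.selected_features), result.best_fitness)
    return result


def stage_evaluate(table: pd.DataFrame, result: TwistResult,
                   cfg: PipelineConfig, out_dir: Path) -> DiagnosticReport:
    report = crossed_evaluation(table, result, k=cfg.k)
    report.predictions.to_csv(out_dir / "predictions.csv", index=False)
    report.to_json(out_dir / "report.json")
    (out_dir / "report.md").write_text(report.to_markdown())
    roc_rows = []
    for name, arm in report.arms.items():
        for fpr, tpr in arm.roc_points:
            roc_rows.append({"arm": name, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_points.csv", index=False)
    log.info("evaluate: pooled accuracy %s, mean AUC %.3f",
             report.pooled_metrics["accuracy"], report.auc_mean)
    return report


def run_all(cfg: PipelineConfig) -> DiagnosticReport:
    """Execute every stage in order, persisting all intermediate artefacts;
    rerunning with the same config reproduces the same report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        cases = stage_simulate(cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc
    if cfg.registration_enabled:
        try:
            cases = stage_register(cases, cfg, out_dir)
        except Exception as exc:
            raise RuntimeError(f"[register] {exc}") from exc
    try:
        table = stage_extract(cases, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[extract] {exc}") from exc
    try:
        result = stage_twist(table, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[twist] {exc}") from exc
    try:
        return stage_evaluate(table, result, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[evaluate] {exc}") from exc


def validate_inputs(series_dir) -> pd.DataFrame:
    """Check a directory of case subdirectories: 5 volumes + 1 mask each,
    consistent shapes/spacings, nonempty mask.  Problems are reported in the
    returned manifest, never raised."""
    import nibabel as nib

    root = Path(series_dir)
    rows = []
    for case_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        problems = []
        vols = []
        for ti in range(5):
            f = case_dir / f"t{ti}.nii.gz"
            if not f.exists():
                problems.append(f"missing t{ti}.nii.gz")
            else:
                img = nib.load(f)
                vols.append((img.shape, tuple(np.round(
                    img.header.get_zooms()[:3], 6))))
        mask_f = case_dir / "mask.nii.gz"
        if not mask_f.exists():
            problems.append("missing mask.nii.gz")
        else:
            mimg = nib.load(mask_f)
            mshape = mimg.shape
            if vols and any(v[0] != vols[0][0] for v in vols):
                problems.append("volume shape mismatch across time-points")
            if vols and mshape != vols[0][0]:
                problems.append("mask shape mismatch")
            if not np.asarray(mimg.dataobj).any():
                problems.append("empty mask")
        if vols and len({v[1] for v in vols}) > 1:
            problems.append("voxel spacing mismatch across time-points")
        rows.append({"case_id": case_dir.name,
                     "status": "ok" if not problems else "fail",
                     "problems": "; ".join(problems)})
    return pd.DataFrame(rows)
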