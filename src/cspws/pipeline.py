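"""Orchestration: cohort generation -> features -> classification -> stats.

A run is fully described by a ``RunConfig``; every random stage has an
explicit seed and a config snapshot is written into the output directory, so
a run is reproducible bit-for-bit from its artifacts.  Stages write:

* ``manifest.csv`` + images/masks (cohort generation)
* ``features.csv`` + ``features.json`` sidecar (per-patient MIL vectors)
* ``cv_result.json`` (repeated stratified CV metrics)
* ``stats_report.json`` + ``patient_d.csv`` (cohort statistics)
* ``run_report.json`` (config snapshot + SHA-256 checksums of all artifacts)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CVConfig, evaluate_repeated_cv, roc_points
from .cohort import CohortSpec, generate_cohort, load_mask_png
from .features import (
    BackboneSpec,
    PreprocConfig,
    aggregate_patient,
    extract_cell_features,
    make_backbone,
    preprocess_nucleus_with_support,
)
from .instrument import load_float_image
from .segmentation import QCConfig, qc_filter
from .stats import (
    age_adjust,
    ancova_d,
    average_d_auc,
    packyear_subgroup_test,
    patient_mean_d,
    subgroup_regression,
)

__all__ = ["RunConfig", "demo_config", "validate_config", "run_pipeline",
           "config_to_yaml", "config_from_yaml"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    cohort: CohortSpec = field(default_factory=CohortSpec)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    stages: tuple[str, ...] = ("simulate", "features", "classify", "stats")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv"] = self.cv.to_dict()
        # the output location is not part of the scientific run description:
        # identical configs in different directories produce identical artifacts
        d.pop("out_dir", None)
        return d


def demo_config(out_dir, seed: int = 0) -> RunConfig:
    """Small profile that runs all stages end-to-end in a few minutes."""
    return RunConfig(
        out_dir=str(out_dir),
        cohort=CohortSpec(
            n_case=10, n_control=10, cells_per_patient=8,
            image_width=256, image_height=192, seed=seed,
        ),
        backbone=BackboneSpec(width_scale=0.25, seed=seed + 1),
        preproc=PreprocConfig(target_size=(112, 112)),
        cv=CVConfig(
            n_folds=4, n_repeats=5, seed=seed + 2, n_keep=40,
            rf_grid=({"n_estimators": 100}, {"n_estimators": 300}),
        ),
    )


def validate_config(config: RunConfig) -> list[str]:
    """All problems found, without side effects; empty list means runnable."""
    problems: list[str] = []
    known = {"simulate", "features", "classify", "stats"}
    for s in config.stages:
        if s not in known:
            problems.append(f"unknown stage {s!r}")
    k = config.backbone.feature_length
    if config.cv.n_keep >= 2 * k:
        problems.append(
            f"cv.n_keep={config.cv.n_keep} is not below the patient feature "
            f"dimension 2k={2 * k}"
        )
    n_min = min(config.cohort.n_case, config.cohort.n_control)
    if n_min < config.cv.n_folds and "classify" in config.stages:
        problems.append(
            f"smaller class ({n_min} patients) cannot be stratified into "
            f"{config.cv.n_folds} folds"
        )
    if config.cohort.cells_per_patient < 2 and "features" in config.stages:
        problems.append("cells_per_patient must be >= 2 for MIL aggregation")
    # negative effect_delta_d is accepted: direction is data, not an error
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _features_stage(out: Path, config: RunConfig) -> tuple[np.ndarray, np.ndarray, list]:
    manifest = pd.read_csv(out / "manifest.csv")
    backbone = make_backbone(config.backbone)
    rows, labels, ids = [], [], []
    for pid, sub in manifest.groupby("patient_id", sort=True):
        feats = []
        for _, row in sub.iterrows():
            img = load_float_image(out / row["image_path"])
            mask = load_mask_png(out / row["mask_path"])
            if not qc_filter(mask, config.qc).keep:
                continue
            pimg, support = preprocess_nucleus_with_support(img, mask, config.preproc)
            feats.append(extract_cell_features(pimg, backbone, support))
        if len(feats) < 2:
            continue
        rows.append(aggregate_patient(feats).values)
        labels.append(1 if sub["group"].iloc[0] == "case" else 0)
        ids.append(pid)
    x = np.asarray(rows)
    fdf = pd.DataFrame(x, index=pd.Index(ids, name="patient_id"))
    fdf.insert(0, "label", labels)
    fdf.to_csv(out / "features.csv")
    (out / "features.json").write_text(
        json.dumps(
            {
                "backbone": config.backbone.to_dict(),
                "preproc": config.preproc.to_dict(),
                "n_patients": len(ids),
                "feature_length": int(x.shape[1]) if len(rows) else 0,
            },
            sort_keys=True,
            indent=1,
        )
    )
    return x, np.asarray(labels), ids


def _stats_stage(out: Path, config: RunConfig) -> dict:
    manifest = pd.read_csv(out / "manifest.csv")
    cells = []
    qc_rows = []
    for _, row in manifest.iterrows():
        img = load_float_image(out / row["image_path"])
        mask = load_mask_png(out / row["mask_path"])
        qc = qc_filter(mask, config.qc)
        qc_rows.append(
            dict(cell_id=row["cell_id"], patient_id=row["patient_id"],
                 area_px=qc.area_px, eccentricity=qc.eccentricity,
                 solidity=qc.solidity, touches_border=qc.touches_border,
                 keep=qc.keep, reject_reason=qc.reject_reason)
        )
        cells.append(
            dict(
                patient_id=row["patient_id"], group=row["group"], site=row["site"],
                age=row["age"], pack_years=row["pack_years"],
                gender=row["gender"], race=row["race"],
                cell_mean_d=float(np.nanmean(img[mask])), keep=qc.keep,
            )
        )
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.csv", index=False)
    table = pd.DataFrame(cells)
    patients = patient_mean_d(table)
    report: dict = {
        "n_patients": len(patients),
        "normalization": "division by control-group mean, per site",
    }
    ctrl_only = [p for p in patients if p.group == "control"]
    try:
        slope, ci = subgroup_regression(patients, "age",
                                        lambda p: p.group == "control")
        report["control_age_slope"] = {"slope": slope, "ci95": list(ci)}
        adjusted, _ = age_adjust(patients, slope)
        report["average_d_auc"] = average_d_auc(patients)
        report["average_d_auc_age_adjusted"] = average_d_auc(patients, adjusted)
    except ValueError as err:
        report["control_age_slope"] = {"error": str(err)}
        report["average_d_auc"] = average_d_auc(patients)
    covs = ["group", "age", "pack_years", "gender", "race"]
    frame = pd.DataFrame(
        {
            "normalized_d": [p.normalized_d for p in patients],
            "group": [p.group for p in patients],
            "age": [p.age for p in patients],
            "pack_years": [p.pack_years for p in patients],
            "gender": [p.gender for p in patients],
            "race": [p.race for p in patients],
        }
    )
    usable = [c for c in covs if frame[c].nunique() > 1]
    try:
        anc = ancova_d(frame[["normalized_d"] + usable], covariates=usable)
        report["ancova"] = {"formula": anc.formula, "terms": anc.terms}
    except ValueError as err:
        report["ancova"] = {"error": str(err)}
    report["packyear_strata"] = packyear_subgroup_test(patients)
    # demographic summary table (covariate, control, case, ANCOVA p)
    per_pat = table.drop_duplicates("patient_id")
    demo_rows = []
    anc_terms = report.get("ancova", {}).get("terms", {})
    for cov in ("age", "pack_years"):
        demo_rows.append(
            dict(covariate=cov,
                 control=f"{per_pat[per_pat.group == 'control'][cov].mean():.1f} "
                         f"+- {per_pat[per_pat.group == 'control'][cov].std():.1f}",
                 case=f"{per_pat[per_pat.group == 'case'][cov].mean():.1f} "
                      f"+- {per_pat[per_pat.group == 'case'][cov].std():.1f}",
                 p_value=anc_terms.get(cov, {}).get("p")))
    for cov, level in (("gender", "F"), ("race", "caucasian")):
        demo_rows.append(
            dict(covariate=f"{cov} (% {level})",
                 control=f"{(per_pat[per_pat.group == 'control'][cov] == level).mean():.0%}",
                 case=f"{(per_pat[per_pat.group == 'case'][cov] == level).mean():.0%}",
                 p_value=anc_terms.get(cov, {}).get("p")))
    pd.DataFrame(demo_rows).to_csv(out / "demographics.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "group": [p.group for p in patients],
            "mean_nuclear_d": [p.mean_nuclear_d for p in patients],
            "normalized_d": [p.normalized_d for p in patients],
            "n_cells": [p.n_cells for p in patients],
        }
    ).to_csv(out / "patient_d.csv", index=False)
    (out / "stats_report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=1)
    )
    artifacts = [out / "run_config.json"]
    if "simulate" in config.stages:
        generate_cohort(config.cohort, out)
        artifacts += [out / "manifest.csv", out / "cohort_spec.json"]
    features = None
    if "features" in config.stages:
        features = _features_stage(out, config)
        artifacts += [out / "features.csv", out / "features.json"]
    if "classify" in config.stages:
        if features is None:
            raise ValueError("classify stage requires the features stage")
        x, y, _ = features
        result = evaluate_repeated_cv(x, y, config.cv)
        result.to_json(out / "cv_result.json")
        # pooled ROC coordinates across all held-out evaluations, for plotting
        pooled_scores = np.concatenate([e.test_scores for e in result.evaluations])
        pooled_labels = np.concatenate([y[e.test_index] for e in result.evaluations])
        pts = roc_points(pooled_scores, pooled_labels)
        pd.DataFrame(pts, columns=["threshold", "fpr", "tpr"]).to_csv(
            out / "roc_coords.csv", index=False
        )
        artifacts += [out / "cv_result.json", out / "roc_coords.csv"]
    if "stats" in config.stages:
        _stats_stage(out, config)
        artifacts += [out / "stats_report.json", out / "patient_d.csv",
                      out / "demographics.csv", out / "qc_report.csv"]
    report = {
        "stages": list(config.stages),
        "checksums": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    (out / "run_report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


def config_to_yaml(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_from_yaml(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cv = dict(raw.get("cv", {}))
    if "rf_grid" in cv:
        cv["rf_grid"] = tuple(dict(g) for g in cv["rf_grid"])
    cohort = dict(raw.get("cohort", {}))
    backbone = dict(raw.get("backbone", {}))
    if "tap_blocks" in backbone:
        backbone["tap_blocks"] = tuple(backbone["tap_blocks"])
    preproc = dict(raw.get("preproc", {}))
    if "target_size" in preproc:
        preproc["target_size"] = tuple(preproc["target_size"])
    return RunConfig(
        out_dir=raw["out_dir"],
        cohort=CohortSpec(**cohort),
        backbone=BackboneSpec(**backbone),
        preproc=PreprocConfig(**preproc),
        qc=QCConfig(**raw.get("qc", {})),
        cv=CVConfig(**cv),
        stages=tuple(raw.get("stages", ("simulate", "features", "classify", "stats"))),
    )
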