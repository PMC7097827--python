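"""End-to-end orchestration: simulate -> preprocess -> register/slice ->
extract -> train -> evaluate -> report, from a single seeded configuration.

The holdout at the top of the protocol is taken at *patient* level (half the
patients, hence half of the 12-per-patient slices, are never seen during
training or model selection); hyperparameter selection and classifier
comparison happen inside the training half by 10-fold cross-validation at
slice level.  Every stage derives its randomness from the three seeds in the
config, so a rerun with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import classify, evaluate, features, preprocess, registration, synthetic
from .synthetic import VIA_NEG, VIA_POS, Grade

__all__ = ["RunConfig", "RunResult", "process_pair", "pair_features",
           "run_pipeline", "compare_classifiers"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run (YAML-serializable)."""

    out_dir: str | None = None
    # seeds
    cohort_seed: int = 0
    split_seed: int = 1
    fold_seed: int = 2
    # generator
    n_patients: int = 20
    fraction_abnormal_patients: float = 0.6
    sectors_per_abnormal: tuple[int, int] = (2, 6)
    image_size: int = 512
    whitening_strength: float = 0.5
    noise_sd: float = 2.0
    n_specular_spots: int = 6
    # preprocessing
    sr_threshold_fraction: float = 0.6
    roi_combine_mode: str = "or"
    # features
    ratio_bins: int = 256
    glcm_levels: int = 8
    glcm_distance: int = 5
    # classification
    families: tuple[str, ...] = ("KNN", "SVM", "DT")
    cv_folds: int = 10
    holdout_fraction: float = 0.5
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "sectors_per_abnormal" in data:
            data["sectors_per_abnormal"] = tuple(data["sectors_per_abnormal"])
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sectors_per_abnormal"] = list(self.sectors_per_abnormal)
        d["families"] = list(self.families)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunResult:
    config: RunConfig
    feature_table: pd.DataFrame
    cv_reports: dict[str, classify.CvReport]
    test_reports: dict[str, classify.CvReport]
    best_family: str
    comparison: pd.DataFrame
    patient_confusion: evaluate.ConfusionMatrix | None
    patient_report: evaluate.AgreementReport | None
    sector_accuracy: float
    train_patients: list[str]
    test_patients: list[str]
    records: list[synthetic.PatientRecord]
    pairs: dict[str, registration.CervicogramPair]


def process_pair(
    record: synthetic.PatientRecord,
    sr_threshold_fraction: float = 0.6,
    roi_combine_mode: str = "or",
) -> tuple[registration.CervicogramPair, list[registration.ClockSlice]]:
    """Preprocess, register and clock-slice one labelled pre/post pair."""
    imgs = {}
    rois = {}
    for phase, px in (("pre", record.pre), ("post", record.post)):
        cg = preprocess.Cervicogram(
            px,
            phase=preprocess.Phase.PRE if phase == "pre" else preprocess.Phase.POST,
            patient_id=record.patient_id,
        )
        sr = preprocess.detect_specular(cg, sr_threshold_fraction)
        cg = preprocess.inpaint_specular(cg, sr)
        imgs[phase] = cg
        rois[phase] = preprocess.bitplane_roi(cg, combine=roi_combine_mode)
    pair = registration.register_pair(
        imgs["pre"], imgs["post"],
        record.fiducials, record.fiducials,
        roi_pre=rois["pre"], roi_post=rois["post"],
    )
    slices = registration.slice_clock(pair)
    slices = registration.attach_labels(slices, record.truth.sector_labels)
    return pair, slices


def pair_features(
    slices: list[registration.ClockSlice],
    ratio_bins: int = 256,
    glcm_levels: int = 8,
    glcm_distance: int = 5,
) -> list[features.FeatureVector]:
    return [
        features.extract_features(
            s, glcm_levels=glcm_levels, glcm_distance=glcm_distance,
            ratio_bins=ratio_bins,
        )
        for s in slices
    ]


def _patient_split(patient_ids: list[str], fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patient_ids))
    n_train = int(np.ceil(len(patient_ids) * fraction))
    ids = [patient_ids[i] for i in order]
    return ids[:n_train], ids[n_train:]


def _report_row(family: str, rep: classify.CvReport) -> dict:
    return {
        "family": family,
        "accuracy": rep.accuracy,
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "kappa": rep.kappa,
        "auc": rep.auc,
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) persist a run directory."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    log.info("stage simulate: %d patients", config.n_patients)
    records = synthetic.generate_cohort(
        n_patients=config.n_patients,
        fraction_abnormal_patients=config.fraction_abnormal_patients,
        sectors_per_abnormal=config.sectors_per_abnormal,
        seed=config.cohort_seed,
        image_size=config.image_size,
        whitening_strength=config.whitening_strength,
        noise_sd=config.noise_sd,
        n_specular_spots=config.n_specular_spots,
    )
    if out:
        synthetic.write_cohort(records, out / "images")

    log.info("stage preprocess/register/extract")
    vectors = []
    pairs: dict[str, registration.CervicogramPair] = {}
    for rec in records:
        pair, slices = process_pair(
            rec, config.sr_threshold_fraction, config.roi_combine_mode
        )
        pairs[rec.patient_id] = pair
        vectors.extend(
            pair_features(
                slices,
                ratio_bins=config.ratio_bins,
                glcm_levels=config.glcm_levels,
                glcm_distance=config.glcm_distance,
            )
        )
    table = features.features_table(vectors)
    n_missing = int(table[list(features.FEATURE_NAMES)].isna().any(axis=1).sum())
    if n_missing:
        log.info("dropping %d slices with missing features from training", n_missing)
    complete = table.dropna(subset=list(features.FEATURE_NAMES)).reset_index(drop=True)
    if out:
        table.to_csv(out / "features.csv", index=False)

    log.info("stage train/compare")
    train_ids, test_ids = _patient_split(
        [r.patient_id for r in records], config.holdout_fraction, config.split_seed
    )
    train = complete[complete.patient_id.isin(train_ids)].reset_index(drop=True)
    test = complete[complete.patient_id.isin(test_ids)].reset_index(drop=True)

    cv_reports = {}
    test_reports = {}
    for family in config.families:
        spec = classify.PAPER_SPECS[family]
        cv_reports[family] = classify.cross_validate(
            train, spec, k=config.cv_folds, seed=config.fold_seed
        )
        params = classify.standardize(train)
        model = classify.train_classifier(params.apply(train), spec,
                                          seed=config.fold_seed)
        test_reports[family] = classify.evaluate_test(model, test, params)

    comparison = (
        pd.DataFrame([_report_row(f, r) for f, r in cv_reports.items()])
        .sort_values(["accuracy", "auc"], ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    best_family = comparison.family.iloc[0]

    log.info("stage evaluate: best family %s", best_family)
    spec = classify.PAPER_SPECS[best_family]
    params = classify.standardize(train)
    model = classify.train_classifier(params.apply(train), spec,
                                      seed=config.fold_seed)
    test_rep = classify.evaluate_test(model, test, params)

    # sector-level truth recovery and patient-level aggregation on held-out
    test_scored = test.copy()
    test_scored["pred"] = np.where(test_rep.predictions, VIA_POS, VIA_NEG)
    sector_accuracy = float(
        100.0 * (test_scored.pred == test_scored.label).mean()
    ) if len(test_scored) else float("nan")

    truth_by_patient = {r.patient_id: r.truth for r in records}
    tp = fn = fp = tn = 0
    for pid in test_ids:
        rows = test_scored[test_scored.patient_id == pid]
        pred = evaluate.aggregate_patient(
            dict(zip(rows.sector, rows.pred))
        )
        true = evaluate.aggregate_patient(truth_by_patient[pid].binary_labels)
        if true == VIA_POS:
            tp += pred == VIA_POS
            fn += pred == VIA_NEG
        else:
            fp += pred == VIA_POS
            tn += pred == VIA_NEG
    patient_cm = None
    patient_rep = None
    if tp + fn + fp + tn:
        patient_cm = evaluate.ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
        patient_rep = evaluate.binary_metrics(patient_cm)

    if out:
        (out / "renders").mkdir(exist_ok=True)
        for pid in test_ids:
            rows = test_scored[test_scored.patient_id == pid]
            preds = dict(zip(rows.sector, rows.pred))
            rec = next(r for r in records if r.patient_id == pid)
            img = evaluate.render_annulus(
                pairs[pid].post.pixels,
                pairs[pid].fiducials.center,
                preds,
                truth_grades=rec.truth.sector_labels,
            )
            Image.fromarray(img).save(out / "renders" / f"{pid}_annulus.png")
        report = {
            "config": dataclasses.asdict(config),
            "counts": {
                "patients": config.n_patients,
                "feature_rows": int(len(table)),
                "complete_rows": int(len(complete)),
                "train_rows": int(len(train)),
                "test_rows": int(len(test)),
            },
            "cv": {f: _report_row(f, r) for f, r in cv_reports.items()},
            "test": {f: _report_row(f, r) for f, r in test_reports.items()},
            "best_family": best_family,
            "sector_accuracy": sector_accuracy,
            "patient": (
                dataclasses.asdict(patient_rep) if patient_rep else None
            ),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return RunResult(
        config=config,
        feature_table=table,
        cv_reports=cv_reports,
        test_reports=test_reports,
        best_family=best_family,
        comparison=comparison,
        patient_confusion=patient_cm,
        patient_report=patient_rep,
        sector_accuracy=sector_accuracy,
        train_patients=train_ids,
        test_patients=test_ids,
        records=records,
        pairs=pairs,
    )


def compare_classifiers(config: RunConfig) -> pd.DataFrame:
    """Cross-validated family comparison, ranked by accuracy then AUC."""
    return run_pipeline(config).comparison
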