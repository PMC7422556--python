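"""End-to-end orchestration of the two experiments.

``run_calibration`` implements the lab arm: per-subject calibration-segment
features -> pooled labelled table -> per-activity scaled-MAD cleaning ->
leave-one-subject-out validation of each classifier family (7-class and
merged 5-class, row-normalized) -> final models refit on all subjects.

``run_validation`` implements the free-living arm: whole-session features
labelled by the observer log, predictions from the lab-trained models,
total-normalized 7- and 5-class confusion charts with margin statistics,
plus the per-workplace-group sub-analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import labels as L
from .evaluate import ConfusionResult, confusion, merge_labels
from .features import (
    FeatureSet,
    OVERLAP_DEFAULT,
    WINDOW_S_DEFAULT,
    build_feature_set,
    concat_feature_sets,
)
from .models import ClassifierSpec, LOSOResult, TrainedModel, loso_validate, predict, train
from .preprocess import DEFAULT_THRESHOLD, OutlierReport, remove_outliers
from .signal_io import AccelRecording, AnnotationLog
from .synthetic import SyntheticConfig, simulate_freeliving_study, simulate_lab_study

logger = logging.getLogger(__name__)

Sessions = list[tuple[AccelRecording, AnnotationLog]]


@dataclass
class PipelineConfig:
    window_s: float = WINDOW_S_DEFAULT
    overlap: float = OVERLAP_DEFAULT
    outlier_threshold: float = DEFAULT_THRESHOLD
    families: tuple[str, ...] = ("rf", "svm", "knn")
    merge: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "overlap": self.overlap,
            "outlier_threshold": self.outlier_threshold,
            "families": list(self.families),
            "merge": self.merge,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)


@dataclass
class CalibrationReport:
    feature_set: FeatureSet
    outlier_reports: list[OutlierReport]
    loso: dict[str, LOSOResult]
    confusions: dict[str, dict[str, ConfusionResult]]  # family -> {"7": ..., "5": ...}
    models: dict[str, TrainedModel]


@dataclass
class ValidationReport:
    confusions: dict[str, dict[str, ConfusionResult]]
    subgroup_confusions: dict[str, dict[str, dict[str, ConfusionResult]]]
    observed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    predicted: dict[str, np.ndarray] = field(default_factory=dict)
    groups: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))


def build_lab_features(sessions: Sessions, cfg: PipelineConfig) -> FeatureSet:
    sets = [
        build_feature_set(rec, log, "lab", cfg.window_s, cfg.overlap)
        for rec, log in sessions
    ]
    fs = concat_feature_sets(sets)
    logger.info("lab features: %d windows from %d subjects", len(fs), len(sessions))
    return fs


def build_freeliving_features(
    sessions: Sessions, cfg: PipelineConfig
) -> tuple[FeatureSet, np.ndarray]:
    """Pooled free-living features plus the per-window workplace-group tags."""
    sets, groups = [], []
    for rec, log in sessions:
        s = build_feature_set(rec, log, "free_living", cfg.window_s, cfg.overlap)
        sets.append(s)
        groups.extend([log.group or ""] * len(s))
    fs = concat_feature_sets(sets)
    logger.info(
        "free-living features: %d windows from %d subjects", len(fs), len(sessions)
    )
    return fs, np.asarray(groups, dtype=object)


def run_calibration(sessions: Sessions, cfg: PipelineConfig) -> CalibrationReport:
    fs = build_lab_features(sessions, cfg)
    fs_clean, reports = remove_outliers(fs, cfg.outlier_threshold)
    logger.info(
        "outlier removal: kept %d of %d windows", len(fs_clean), len(fs)
    )
    loso: dict[str, LOSOResult] = {}
    confusions: dict[str, dict[str, ConfusionResult]] = {}
    models: dict[str, TrainedModel] = {}
    for family in cfg.families:
        spec = ClassifierSpec(family=family, seed=cfg.seed)
        res = loso_validate(fs_clean, spec)
        loso[family] = res
        by_classes = {
            "7": confusion(res.observed, res.predicted, L.SEVEN_CLASSES, "row")
        }
        if cfg.merge:
            by_classes["5"] = confusion(
                merge_labels(res.observed),
                merge_labels(res.predicted),
                L.FIVE_CLASSES,
                "row",
            )
        confusions[family] = by_classes
        models[family] = train(fs_clean, spec)
        logger.info(
            "lab LOSO %s: 7-class accuracy %.3f%s",
            family,
            by_classes["7"].accuracy,
            f", 5-class {by_classes['5'].accuracy:.3f}" if cfg.merge else "",
        )
    return CalibrationReport(fs_clean, reports, loso, confusions, models)


def run_validation(
    models: dict[str, TrainedModel], sessions: Sessions, cfg: PipelineConfig
) -> ValidationReport:
    fs, groups = build_freeliving_features(sessions, cfg)
    observed = fs.y
    confusions: dict[str, dict[str, ConfusionResult]] = {}
    subgroup: dict[str, dict[str, dict[str, ConfusionResult]]] = {}
    predicted: dict[str, np.ndarray] = {}
    group_names = sorted(g for g in set(groups) if g)
    for family, model in models.items():
        preds = predict(model, fs)
        predicted[family] = preds
        by_classes = {"7": confusion(observed, preds, L.SEVEN_CLASSES, "total")}
        if cfg.merge:
            by_classes["5"] = confusion(
                merge_labels(observed), merge_labels(preds), L.FIVE_CLASSES, "total"
            )
        confusions[family] = by_classes
        subgroup[family] = {}
        for g in group_names:
            mask = groups == g
            sub = {
                "7": confusion(observed[mask], preds[mask], L.SEVEN_CLASSES, "total")
            }
            if cfg.merge:
                sub["5"] = confusion(
                    merge_labels(observed[mask]),
                    merge_labels(preds[mask]),
                    L.FIVE_CLASSES,
                    "total",
                )
            subgroup[family][g] = sub
        logger.info(
            "free-living %s: 7-class accuracy %.3f%s",
            family,
            by_classes["7"].accuracy,
            f", 5-class {by_classes['5'].accuracy:.3f}" if cfg.merge else "",
        )
    return ValidationReport(confusions, subgroup, observed, predicted, groups)


def run_synthetic_study(
    pipeline_cfg: PipelineConfig,
    n_lab: int = 35,
    n_freeliving: int = 29,
) -> tuple[CalibrationReport, ValidationReport]:
    """Generate the default synthetic study and run both experiments."""
    lab_cfg = SyntheticConfig(n_subjects=n_lab, seed=pipeline_cfg.seed)
    fl_cfg = SyntheticConfig(n_subjects=n_freeliving, seed=pipeline_cfg.seed + 1)
    lab_sessions = simulate_lab_study(lab_cfg)
    fl_sessions = simulate_freeliving_study(fl_cfg)
    cal = run_calibration(lab_sessions, pipeline_cfg)
    val = run_validation(cal.models, fl_sessions, pipeline_cfg)
    return cal, val


def report_to_dict(
    cfg: PipelineConfig, cal: CalibrationReport, val: ValidationReport | None
) -> dict:
    """JSON-serializable run report (config snapshot + all confusions)."""
    out: dict = {
        "config": cfg.to_dict(),
        "outliers": [
            {
                "activity": r.activity,
                "n_before": r.n_before,
                "n_removed": r.n_removed,
            }
            for r in cal.outlier_reports
        ],
        "lab": {
            family: {k: cr.to_dict() for k, cr in by.items()}
            for family, by in cal.confusions.items()
        },
    }
    if val is not None:
        out["free_living"] = {
            family: {k: cr.to_dict() for k, cr in by.items()}
            for family, by in val.confusions.items()
        }
        out["free_living_subgroups"] = {
            family: {
                g: {k: cr.to_dict() for k, cr in by.items()}
                for g, by in groups.items()
            }
            for family, groups in val.subgroup_confusions.items()
        }
    return out


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
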