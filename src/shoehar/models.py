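"""The three classifier families and leave-one-subject-out validation.

The families mirror a common activity-recognition toolbox setup:

* ``rf`` — an ensemble of 100 bagged decision trees (random forest),
* ``svm`` — a cubic-polynomial-kernel SVM, one-vs-one multiclass, box
  constraint C=1, on standardized features,
* ``knn`` — 10 nearest neighbours weighted by inverse squared Euclidean
  distance, on standardized features.

Validation is leave-one-subject-out (LOSO): each fold trains on every window
from all other subjects and predicts the held-out subject's windows, so no
subject ever contributes to both sides of a fold. Standardization is refit
inside every fold to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSet

FAMILIES = ("rf", "svm", "knn")

_PERSIST_SCHEMA = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of one model family.

    ``seed`` drives every stochastic component; LOSO fold ``f`` uses
    ``seed + f`` so folds are independent but reproducible.
    """

    family: str = "rf"
    n_trees: int = 100
    svm_degree: int = 3
    svm_c: float = 1.0
    knn_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.n_trees < 1 or self.knn_k < 1:
            raise ValueError("n_trees and knn_k must be >= 1")
        if self.svm_degree != 3:
            raise ValueError("svm kernel degree is fixed at 3")


def _inverse_squared_distance(dist: np.ndarray) -> np.ndarray:
    """KNN weights 1/d^2; rows containing an exact-match neighbour put all
    weight on the zero-distance neighbours (the limit of 1/d^2)."""
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist**2)
    exact = np.isinf(w)
    rows = exact.any(axis=1)
    w[rows] = exact[rows].astype(float)
    return w


def _build_estimator(spec: ClassifierSpec, seed: int) -> Pipeline:
    if spec.family == "rf":
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed, n_jobs=1
        )
        steps = [("clf", clf)]
    elif spec.family == "svm":
        clf = SVC(
            kernel="poly",
            degree=spec.svm_degree,
            C=spec.svm_c,
            decision_function_shape="ovo",
            random_state=seed,
        )
        steps = [("scale", StandardScaler()), ("clf", clf)]
    else:  # knn
        clf = KNeighborsClassifier(
            n_neighbors=spec.knn_k,
            weights=_inverse_squared_distance,
            metric="euclidean",
        )
        steps = [("scale", StandardScaler()), ("clf", clf)]
    return Pipeline(steps)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    pipeline: Pipeline

    @property
    def standardization(self) -> tuple[np.ndarray, np.ndarray] | None:
        """Per-feature (mean, SD) learned from the training windows, if the
        family standardizes."""
        if "scale" in self.pipeline.named_steps:
            sc: StandardScaler = self.pipeline.named_steps["scale"]
            return sc.mean_, sc.scale_
        return None

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "schema": _PERSIST_SCHEMA,
                "spec": self.spec,
                "classes": self.classes,
                "feature_names": self.feature_names,
                "pipeline": self.pipeline,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("schema") != _PERSIST_SCHEMA:
            raise ValueError(f"unsupported model archive schema {blob.get('schema')}")
        return cls(blob["spec"], blob["classes"], blob["feature_names"], blob["pipeline"])


def train(fs: FeatureSet, spec: ClassifierSpec, seed: int | None = None) -> TrainedModel:
    """Fit one classifier on a labelled feature set.

    Raises on single-class input and, for KNN, when there are fewer windows
    than neighbours.
    """
    X, y = fs.X, fs.y
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if spec.family == "knn" and len(y) < spec.knn_k:
        raise ValueError(
            f"knn needs at least k={spec.knn_k} training windows, got {len(y)}"
        )
    est = _build_estimator(spec, spec.seed if seed is None else seed)
    est.fit(X, y.astype(str))
    return TrainedModel(spec, classes, fs.feature_names, est)


def predict(model: TrainedModel, fs: FeatureSet) -> np.ndarray:
    """Predict one label per window; labels come from the training vocabulary."""
    if fs.feature_names != model.feature_names:
        raise ValueError("feature names differ from the model's training features")
    if len(fs) == 0:
        return np.empty(0, dtype=object)
    return model.pipeline.predict(fs.X).astype(object)


@dataclass
class LOSOResult:
    """Pooled leave-one-subject-out predictions.

    ``folds`` records, per held-out subject, the sorted set of training
    subjects actually used — kept so the no-leakage invariant can be audited.
    """

    spec: ClassifierSpec
    subjects: tuple[str, ...]
    observed: np.ndarray
    predicted: np.ndarray
    window_subjects: np.ndarray
    folds: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.observed == self.predicted))


def loso_validate(fs: FeatureSet, spec: ClassifierSpec) -> LOSOResult:
    """Leave-one-subject-out validation of one classifier spec.

    Each fold refits the full pipeline (including standardization) on the
    remaining subjects. Every input window appears exactly once in the pooled
    (observed, predicted) pairs, ordered by subject then time.
    """
    subj = fs.subjects
    subjects = tuple(sorted(set(subj)))
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    obs_parts, pred_parts, subj_parts = [], [], []
    folds: dict[str, tuple[str, ...]] = {}
    for f, held_out in enumerate(subjects):
        train_mask = subj != held_out
        test_mask = ~train_mask
        train_fs = fs.subset(train_mask)
        model = train(train_fs, spec, seed=spec.seed + f)
        test_fs = fs.subset(test_mask)
        preds = predict(model, test_fs)
        obs_parts.append(test_fs.y)
        pred_parts.append(preds)
        subj_parts.append(test_fs.subjects)
        folds[held_out] = tuple(sorted(set(train_fs.subjects)))
    return LOSOResult(
        spec=spec,
        subjects=subjects,
        observed=np.concatenate(obs_parts),
        predicted=np.concatenate(pred_parts),
        window_subjects=np.concatenate(subj_parts),
        folds=folds,
    )
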