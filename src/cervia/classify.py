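"""Classifier training and comparison with holdout + 10-fold cross-validation.

The feature table is shuffled and split in half; hyperparameters are chosen
inside the training half by 10-fold cross-validation (standardization re-fit
on each fold's nine training subsamples so no information leaks into the
held-out fold), and the untouched half serves as the final test set.  Three
families are compared, with the published defaults:

* KNN — 5 neighbours, Euclidean distance; the positive score is the
  positive-neighbour fraction.
* SVM — 4th-degree polynomial kernel, cost 3, gamma 2.2; scores are a
  rank-preserving logistic squash of the decision values (a decision value
  of 0 maps to score 0.5, so the common 0.5 threshold applies everywhere).
* Decision tree — Gini splits grown best-first, capped at 20 total nodes
  (internal + leaves); the score is the leaf positive fraction.

Summary metrics are computed from the pooled held-out scores at threshold
0.5, and ROC/AUC by sweeping all score thresholds (trapezoidal area, which
equals the Mann-Whitney pair-counting statistic with ties counted half).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import ConfusionMatrix, binary_metrics, cohen_kappa
from .features import FEATURE_NAMES
from .synthetic import VIA_POS

__all__ = [
    "ClassifierSpec",
    "StandardizationParams",
    "CvReport",
    "TrainedModel",
    "holdout_split",
    "standardize",
    "cross_validate",
    "grid_search",
    "train_classifier",
    "evaluate_test",
    "roc_auc",
    "PAPER_SPECS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameters."""

    family: str  # "KNN" | "SVM" | "DT"
    knn_k: int = 5
    svm_degree: int = 4
    svm_cost: float = 3.0
    svm_gamma: float = 2.2
    dt_max_nodes: int = 20

    def __post_init__(self) -> None:
        if self.family not in ("KNN", "SVM", "DT"):
            raise ValueError("family must be KNN, SVM or DT")
        if self.family == "KNN" and (self.knn_k < 1 or self.knn_k % 2 == 0):
            raise ValueError("knn_k must be odd and >= 1 (no vote ties)")
        if self.family == "SVM" and (self.svm_cost <= 0 or self.svm_gamma <= 0):
            raise ValueError("svm_cost and svm_gamma must be positive")
        if self.family == "DT" and self.dt_max_nodes < 2:
            raise ValueError("dt_max_nodes must be >= 2")


#: the published configurations for the three families
PAPER_SPECS = {
    "KNN": ClassifierSpec("KNN", knn_k=5),
    "SVM": ClassifierSpec("SVM", svm_degree=4, svm_cost=3.0, svm_gamma=2.2),
    "DT": ClassifierSpec("DT", dt_max_nodes=20),
}


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature centre and scale learned from training rows only."""

    center: pd.Series
    scale: pd.Series
    weights: np.ndarray | None = None

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        cols = list(self.center.index)
        out[cols] = (out[cols] - self.center) / self.scale
        return out


@dataclass
class CvReport:
    """Pooled held-out performance of one classifier."""

    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    auc: float
    roc_points: np.ndarray
    per_sample_scores: np.ndarray
    predictions: np.ndarray
    confusion: ConfusionMatrix
    warnings: list[str] = field(default_factory=list)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    feature_names: tuple[str, ...]

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Positive-class score in [0, 1] for every row (standardized input)."""
        X = table[list(self.feature_names)].to_numpy(dtype=float)
        if self.spec.family == "SVM":
            d = self.estimator.decision_function(X)
            return 1.0 / (1.0 + np.exp(-d))  # monotone; 0 -> 0.5
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(True)
        return proba[:, pos]


def _labels(table: pd.DataFrame) -> np.ndarray:
    return (table["label"] == VIA_POS).to_numpy()


def holdout_split(
    table: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle rows with the seed and split; training gets ceil(n*fraction)."""
    if len(table) < 20:
        raise ValueError("need at least 20 labelled rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    n_train = int(np.ceil(len(table) * fraction))
    train = table.iloc[order[:n_train]].reset_index(drop=True)
    test = table.iloc[order[n_train:]].reset_index(drop=True)
    for name, part in (("train", train), ("test", test)):
        if len(part) and _labels(part).all() or len(part) and not _labels(part).any():
            log.warning("%s split contains a single class; some metrics undefined", name)
    return train, test


def standardize(
    train: pd.DataFrame,
    columns=FEATURE_NAMES,
    sample_weight: np.ndarray | None = None,
) -> StandardizationParams:
    """Fit per-feature z-scoring (optionally weighted) on training rows.

    The published protocol standardizes predictors by their (weighted) means
    and standard deviations; no sample weights are defined anywhere in it, so
    the default is uniform weights, with the hook exposed.
    """
    cols = list(columns)
    X = train[cols].to_numpy(dtype=float)
    if sample_weight is None:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
    else:
        w = np.asarray(sample_weight, dtype=float)
        center = np.average(X, axis=0, weights=w)
        scale = np.sqrt(np.average((X - center) ** 2, axis=0, weights=w))
    for c, s in zip(cols, scale):
        if s <= 0:
            raise ValueError(f"feature {c!r} has zero spread in the training data")
    return StandardizationParams(
        center=pd.Series(center, index=cols),
        scale=pd.Series(scale, index=cols),
        weights=sample_weight,
    )


def _make_estimator(spec: ClassifierSpec, seed: int = 0):
    if spec.family == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    if spec.family == "SVM":
        return SVC(
            kernel="poly",
            degree=spec.svm_degree,
            C=spec.svm_cost,
            gamma=spec.svm_gamma,
        )
    # best-first growth: a binary tree with m leaves has 2m - 1 total nodes
    max_leaves = max(2, (spec.dt_max_nodes + 1) // 2)
    return DecisionTreeClassifier(
        criterion="gini", max_leaf_nodes=max_leaves, random_state=seed
    )


def train_classifier(
    train: pd.DataFrame, spec: ClassifierSpec, seed: int = 0
) -> TrainedModel:
    """Fit one classifier on an (already standardized) training table."""
    y = _labels(train)
    if y.all() or not y.any():
        raise ValueError("training data contains a single class")
    est = _make_estimator(spec, seed)
    est.fit(train[list(FEATURE_NAMES)].to_numpy(dtype=float), y)
    return TrainedModel(spec=spec, estimator=est, feature_names=FEATURE_NAMES)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all thresholds and the trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney statistic
    U / (n+ * n-) with tied scores counted half.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _report_from_scores(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5,
                        warnings_: list[str] | None = None) -> CvReport:
    pred = scores >= threshold
    cm = ConfusionMatrix(
        tp=int((pred & y).sum()),
        fn=int((~pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
    )
    m = binary_metrics(cm)
    kappa = cohen_kappa(cm).kappa if 0 < y.sum() < y.size else float("nan")
    if 0 < y.sum() < y.size:
        roc_points, auc = roc_auc(scores, y)
    else:
        roc_points, auc = np.empty((0, 2)), float("nan")
    return CvReport(
        accuracy=m.accuracy,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        kappa=kappa,
        auc=auc,
        roc_points=roc_points,
        per_sample_scores=scores,
        predictions=pred,
        confusion=cm,
        warnings=warnings_ or [],
    )


def cross_validate(
    train: pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    refit_standardization: bool = True,
) -> CvReport:
    """k-fold cross-validation with leak-free per-fold standardization.

    Rows are shuffled with the seed and divided into k folds of size
    floor(n/k) or ceil(n/k); each sample is scored exactly once, from the
    fold where it was held out, and summary metrics are computed from the
    pooled held-out scores at threshold 0.5.  ``refit_standardization=False``
    fits the z-scoring once on the full training table instead (a possible
    shortcut in the original protocol, exposed for comparison).
    """
    n = len(train)
    if k > n:
        raise ValueError("k cannot exceed the number of training rows")
    y = _labels(train)
    if y.all() or not y.any():
        raise ValueError("cross-validation requires both classes")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    scores = np.full(n, np.nan)
    warns: list[str] = []
    global_params = None if refit_standardization else standardize(train)
    for i, val_idx in enumerate(folds):
        mask = np.zeros(n, dtype=bool)
        mask[val_idx] = True
        fit_part = train.loc[~mask].reset_index(drop=True)
        val_part = train.loc[mask].reset_index(drop=True)
        yv = y[mask]
        if yv.all() or not yv.any():
            warns.append(f"fold {i}: single-class validation fold")
        params = standardize(fit_part) if refit_standardization else global_params
        model = train_classifier(params.apply(fit_part), spec, seed=seed)
        scores[mask] = model.scores(params.apply(val_part))
    return _report_from_scores(scores, y, warnings_=warns)


def grid_search(
    train: pd.DataFrame,
    family: str,
    grid: dict[str, list],
    k: int = 10,
    seed: int = 0,
) -> ClassifierSpec:
    """Exhaustive hyperparameter search by cross-validated accuracy.

    Ties are broken by higher AUC, then by earlier grid order; selection is
    deterministic for a fixed seed.  Invalid grid points are skipped with a
    log entry.
    """
    keys = list(grid)
    if not keys or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    best = None
    for values in itertools.product(*(grid[k_] for k_ in keys)):
        try:
            spec = ClassifierSpec(family, **dict(zip(keys, values)))
            report = cross_validate(train, spec, k=k, seed=seed)
        except ValueError as exc:
            log.info("skipping grid point %s: %s", dict(zip(keys, values)), exc)
            continue
        key = (report.accuracy, report.auc)
        if best is None or key > best[0]:
            best = (key, spec)
    if best is None:
        raise ValueError("no valid grid point")
    return best[1]


def evaluate_test(
    model: TrainedModel, test: pd.DataFrame, params: StandardizationParams
) -> CvReport:
    """Score a held-out table with train-set standardization parameters."""
    if not len(test):
        raise ValueError("test table is empty")
    complete = test[list(FEATURE_NAMES)].notna().all(axis=1)
    if not complete.all():
        log.warning("skipping %d test rows with missing features", (~complete).sum())
        test = test.loc[complete].reset_index(drop=True)
    scores = model.scores(params.apply(test))
    return _report_from_scores(scores, _labels(test))
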