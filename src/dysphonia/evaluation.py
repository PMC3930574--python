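"""Cross-validated evaluation of the dysphonia classifiers.

Orchestrates k-fold cross-validation of the full pipeline (kernel-parameter,
bandwidth and SVM hyperparameter searches nested inside the training folds by
default), pools held-out predictions into a single confusion matrix, and
reports accuracy, sensitivity, specificity, the ROC curve with trapezoidal
AUC, and per-subject misclassification counts. PD is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import baselines, density_map, kpca
from .data_io import LABEL_CO, LABEL_PD, FeatureTable, SubjectInfo, canonical_measure_name
from .feature_selection import sfs_select


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with PD as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)


def confusion_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    labels, predicted = np.asarray(labels), np.asarray(predicted)
    return ConfusionCounts(
        TP=int(((labels == LABEL_PD) & (predicted == LABEL_PD)).sum()),
        FN=int(((labels == LABEL_PD) & (predicted == LABEL_CO)).sum()),
        TN=int(((labels == LABEL_CO) & (predicted == LABEL_CO)).sum()),
        FP=int(((labels == LABEL_CO) & (predicted == LABEL_PD)).sum()),
    )


def roc_curve(labels: np.ndarray, scores: np.ndarray
              ) -> tuple[list[tuple[float, float, float]], float]:
    """Threshold sweep ROC with trapezoidal AUC; larger score = more PD-like.

    Returns ``([(threshold, FPR, TPR), ...], auc)``; thresholds include an
    infinite endpoint so the curve spans (0,0)-(1,1). AUC is invariant under
    any strictly increasing transform of the scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for an ROC curve")
    if np.ptp(scores) == 0:
        warnings.warn("constant decision scores: ROC is the chance diagonal", stacklevel=2)
        return [(np.inf, 0.0, 0.0), (scores[0], 1.0, 1.0)], 0.5
    y = (labels == LABEL_PD).astype(int)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    points = [(float(t), float(f), float(s)) for t, f, s in zip(thr, fpr, tpr)]
    return points, float(_trapezoid_auc(fpr, tpr))


def make_folds(table: FeatureTable, k: int, seed: int,
               strategy: str = "stratified_record") -> np.ndarray:
    """Assign each record to one of k disjoint, exhaustive folds.

    ``stratified_record`` preserves class ratios within one record per fold;
    ``grouped_subject`` keeps all of a subject's records in the same fold
    (guarding against subject-identity leakage, since each subject contributed
    several records).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(table)
    assignment = np.full(n, -1, dtype=int)
    if strategy == "stratified_record":
        counts = table.class_counts()
        if min(counts.values()) < k:
            raise ValueError("cannot stratify: a class has fewer records than folds")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), table.y())):
            assignment[test_idx] = fold
    elif strategy == "grouped_subject":
        subjects = list(dict.fromkeys(table.subject_ids))
        rng = np.random.default_rng(seed)
        rng.shuffle(subjects)
        sizes = {s: table.subject_ids.count(s) for s in subjects}
        # largest subjects first onto the currently lightest fold
        fold_load = [0] * k
        fold_of = {}
        for s in sorted(subjects, key=lambda s: -sizes[s]):
            f = int(np.argmin(fold_load))
            fold_of[s] = f
            fold_load[f] += sizes[s]
        for i, s in enumerate(table.subject_ids):
            assignment[i] = fold_of[s]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    assert (assignment >= 0).all()
    return assignment


@dataclass
class PipelineConfig:
    """What run_cv trains inside each fold.

    ``measures`` are the input vocal measures; with ``select_features`` they
    are re-selected by SFS inside each training fold instead.
    ``feature_space`` is "kpca" (project measures by polynomial KPCA) or
    "raw" (use the measures directly as the 2-D plane; requires exactly two).
    Search fields set to None trigger the nested grid searches.
    """

    classifier: str = "map"  # map | flda | svm
    measures: list[str] | None = None
    select_features: bool = False
    feature_space: str = "kpca"
    kernel_params: kpca.KernelParams | None = None  # None -> grid search
    grid_d: tuple = tuple(range(1, 11))
    grid_c: tuple = tuple(range(1, 11))
    h: float | None = None  # None -> leave-one-out search
    priors: str = "empirical"
    svm_C: float | None = None  # None -> nested tuning
    svm_gamma: float | None = None
    global_fit: bool = False  # searches on all data first instead of per fold

    def __post_init__(self) -> None:
        if self.classifier not in ("map", "flda", "svm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.feature_space not in ("kpca", "raw"):
            raise ValueError(f"unknown feature space {self.feature_space!r}")


@dataclass
class CVReport:
    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    roc: list[tuple[float, float, float]]
    auc: float
    per_subject_failures: dict[str, int]
    fold_assignment: dict[str, int]
    seed: int
    mode: str  # "nested" or "global_fit"
    predictions: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    fold_metrics: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.confusion.TP, "FN": self.confusion.FN,
                          "TN": self.confusion.TN, "FP": self.confusion.FP},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "per_subject_failures": self.per_subject_failures,
            "seed": self.seed,
            "mode": self.mode,
        }


def _fit_predict(train: FeatureTable, test: FeatureTable, measures: list[str],
                 config: PipelineConfig, seed: int,
                 fixed: dict) -> tuple[np.ndarray, np.ndarray]:
    """Fit the configured pipeline on the training fold, score the test fold.

    Returns (predicted labels, continuous decision scores) for the test fold.
    """
    if config.feature_space == "kpca":
        params = fixed.get("kernel_params") or config.kernel_params
        if params is None:
            params, _ = kpca.select_kernel_params(train, measures,
                                                  config.grid_d, config.grid_c)
        model = kpca.fit_kpca(train.matrix(measures), params, labels=train.labels)
        z_train, z_test = model.training_scores, model.transform(test.matrix(measures))
    else:
        if len(measures) != 2:
            raise ValueError("raw feature space requires exactly two measures")
        z_train, z_test = train.matrix(measures), test.matrix(measures)

    if config.classifier == "map":
        h = fixed.get("h") or config.h
        if h is None:
            h = density_map.select_bandwidth(z_train, train.labels).h
        kde = density_map.fit_kde(z_train, train.labels, h, config.priors)
        score = density_map.pd_posterior(kde, z_test)
        pred = np.array([r.predicted for r in density_map.posterior_batch(kde, z_test)])
    elif config.classifier == "flda":
        flda = baselines.fit_flda(z_train, train.labels)
        score = flda.decision(z_test)
        pred = flda.predict(z_test)
    else:
        C, g = fixed.get("svm", (config.svm_C, config.svm_gamma))
        if C is None or g is None:
            C, g = baselines.tune_svm(z_train, train.labels, seed=seed)
        svm = baselines.fit_svm(z_train, train.labels, C, g)
        score = svm.decision(z_test)
        pred = svm.predict(z_test)
    return pred, np.asarray(score, dtype=float)


def run_cv(table: FeatureTable, config: PipelineConfig, folds: int = 5,
           seed: int = 0, strategy: str = "stratified_record") -> CVReport:
    """k-fold cross-validation of the configured pipeline.

    Model selection (kernel parameters, KDE bandwidth, SVM hyperparameters)
    runs on the training folds only by default; ``config.global_fit`` runs
    the searches once on all data first. Held-out predictions are pooled into
    a single confusion matrix and ROC.
    """
    if config.measures is None and not config.select_features:
        raise ValueError("config must name measures or enable select_features")
    assignment = make_folds(table, folds, seed, strategy)
    fixed: dict = {}
    if config.global_fit:
        measures_all = config.measures
        if config.select_features:
            measures_all = sfs_select(table, seed=seed).selected
        if config.feature_space == "kpca" and config.kernel_params is None:
            fixed["kernel_params"], _ = kpca.select_kernel_params(
                table, measures_all, config.grid_d, config.grid_c)
        if config.classifier == "map" and config.h is None:
            params = fixed.get("kernel_params") or config.kernel_params
            if config.feature_space == "kpca":
                m = kpca.fit_kpca(table.matrix(measures_all), params, labels=table.labels)
                z_all = m.training_scores
            else:
                z_all = table.matrix(measures_all)
            fixed["h"] = density_map.select_bandwidth(z_all, table.labels).h
        if config.classifier == "svm" and (config.svm_C is None or config.svm_gamma is None):
            fixed["svm"] = (None, None)  # still tuned per fold: scores are fold-specific

    n = len(table)
    predicted = np.empty(n, dtype=object)
    dec_scores = np.empty(n, dtype=float)
    fold_metrics = []
    for fold in range(folds):
        test_idx = np.where(assignment == fold)[0]
        train_idx = np.where(assignment != fold)[0]
        train, test = table.subset(train_idx), table.subset(test_idx)
        if len(set(train.labels)) < 2:
            raise ValueError(f"training folds for fold {fold} contain a single class")
        measures = config.measures
        if config.select_features:
            measures = sfs_select(train, seed=seed).selected
        measures = [canonical_measure_name(m) for m in measures]
        pred, score = _fit_predict(train, test, measures, config, seed, fixed)
        predicted[test_idx] = pred
        dec_scores[test_idx] = score
        cm = confusion_from_predictions(test.labels, pred)
        fold_metrics.append({"fold": fold, "accuracy": cm.accuracy, "n": len(test)})

    labels = table.labels
    confusion = confusion_from_predictions(labels, predicted)
    roc, auc_value = roc_curve(labels, dec_scores)
    failures: dict[str, int] = {}
    for rec, pred in zip(table.records, predicted):
        if pred != rec.label:
            failures[rec.subject_id] = failures.get(rec.subject_id, 0) + 1
    return CVReport(
        confusion=confusion,
        accuracy=confusion.accuracy,
        sensitivity=confusion.sensitivity,
        specificity=confusion.specificity,
        roc=roc,
        auc=auc_value,
        per_subject_failures=dict(sorted(failures.items())),
        fold_assignment={rid: int(f) for rid, f in zip(table.record_ids, assignment)},
        seed=seed,
        mode="global_fit" if config.global_fit else "nested",
        predictions={rid: str(p) for rid, p in zip(table.record_ids, predicted)},
        scores={rid: float(s) for rid, s in zip(table.record_ids, dec_scores)},
        fold_metrics=fold_metrics,
    )


def failure_report(report: CVReport, subjects: dict[str, SubjectInfo] | None = None
                   ) -> pd.DataFrame:
    """One row per subject with >= 1 misclassified record, sorted by subject id,
    joined with optional demographic/severity metadata."""
    subjects = subjects or {}
    rows = []
    for sid in sorted(report.per_subject_failures):
        info = subjects.get(sid)
        rows.append({
            "subject_id": sid,
            "failure_records": report.per_subject_failures[sid],
            "gender": info.gender if info else "unknown",
            "age": info.age if info else None,
            "group": info.group if info else None,
            "hy_stage": info.hy_stage if info else None,
        })
    return pd.DataFrame(rows, columns=["subject_id", "failure_records", "gender",
                                       "age", "group", "hy_stage"])
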