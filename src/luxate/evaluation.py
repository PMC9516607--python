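"""Stratified cross-validated evaluation of the full pipeline.

Per fold: standardization, (by default) feature selection and the
Gaussian naive Bayes fit are all learned on the training part only,
then both parts are scored. Reported metrics are accuracy and
support-weighted precision/recall/F1 — with weighted averaging, recall
is identically equal to accuracy. On top of the usual metrics, two
clinically motivated rates are computed on the pooled test
predictions: the fraction with the correct jaw, and the fraction
predicted either exactly right or as a neighboring tooth class in the
same jaw. Confusion matrices accumulate over folds, so the test matrix
totals n and the train matrix totals (k-1) * n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold

from .classifier import gnb_fit, gnb_predict
from .config import RunConfig
from .core import LABEL_CODES, RawRecording, ToothLabel, neighbor_of, same_jaw
from .features import build_catalogue, feature_matrix
from .preprocessing import preprocess
from .selection import l2_importances, select, standardize_apply, standardize_fit


@dataclass
class FoldAssignment:
    """Fold id per sample for a stratified k-fold split."""

    fold_ids: np.ndarray
    k: int
    seed: int

    def split(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(self.k):
            test = np.flatnonzero(self.fold_ids == f)
            train = np.flatnonzero(self.fold_ids != f)
            yield train, test


def stratified_kfold(y, k: int = 4, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment.

    Fold sizes differ by at most one sample overall and per label.
    Labels rarer than k still get assigned but trigger a warning since
    some folds will lack them entirely.
    """
    y = np.asarray(y)
    if k > y.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples ({y.shape[0]})")
    codes, counts = np.unique(y, return_counts=True)
    rare = codes[counts < k]
    if rare.size:
        warnings.warn(
            f"labels with fewer than k={k} samples: {list(map(str, rare))}",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = np.empty(y.shape[0], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for f, (_, test) in enumerate(skf.split(np.zeros((y.shape[0], 1)), y)):
            fold_ids[test] = f
    return FoldAssignment(fold_ids=fold_ids, k=k, seed=seed)


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def classification_metrics(y_true, y_pred) -> Metrics:
    """Accuracy plus support-weighted precision/recall/F1.

    Labels never predicted contribute precision 0 (no division
    warnings). Weighted recall equals accuracy by construction.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.shape[0] == 0:
        raise ValueError("empty label arrays")
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0
    )
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
    )


def cumulative_confusion(
    fold_pairs: list[tuple[np.ndarray, np.ndarray]],
    labels: tuple[str, ...] = LABEL_CODES,
) -> pd.DataFrame:
    """Sum of per-fold confusion matrices in canonical label order.

    Rows are true labels, columns predictions; the diagonal holds the
    correctly predicted counts.
    """
    total = np.zeros((len(labels), len(labels)), dtype=int)
    for y_true, y_pred in fold_pairs:
        total += confusion_matrix(y_true, y_pred, labels=list(labels))
    return pd.DataFrame(total, index=list(labels), columns=list(labels))


def _as_label(x) -> ToothLabel:
    return x if isinstance(x, ToothLabel) else ToothLabel.from_code(str(x))


def clinical_rates(y_true, y_pred) -> tuple[float, float]:
    """(jaw-correct rate, correct-or-neighboring rate).

    Both rates dominate plain accuracy: an exact prediction is in the
    right jaw and is trivially "correct or neighboring".
    """
    y_true = [_as_label(x) for x in y_true]
    y_pred = [_as_label(x) for x in y_pred]
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if not y_true:
        raise ValueError("empty label arrays")
    jaw = sum(same_jaw(t, p) for t, p in zip(y_true, y_pred))
    near = sum(t == p or neighbor_of(t, p) for t, p in zip(y_true, y_pred))
    n = len(y_true)
    return jaw / n, near / n


@dataclass
class CVReport:
    """Everything a cross-validated run produced."""

    fold_sizes_train: list[int]
    fold_sizes_test: list[int]
    train_metrics: list[Metrics]
    test_metrics: list[Metrics]
    train_confusion: pd.DataFrame
    test_confusion: pd.DataFrame
    jaw_correct_rate: float
    neighbor_or_correct_rate: float
    n_selected_per_fold: list[int]
    selected_names_per_fold: list[list[str]]
    config: dict = field(default_factory=dict)

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.train_metrics]))

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.test_metrics]))

    @property
    def cumulative_test_accuracy(self) -> float:
        m = self.test_confusion.to_numpy()
        return float(np.trace(m) / m.sum())

    @property
    def cumulative_train_accuracy(self) -> float:
        m = self.train_confusion.to_numpy()
        return float(np.trace(m) / m.sum())

    def to_dict(self) -> dict:
        return {
            "fold_sizes_train": self.fold_sizes_train,
            "fold_sizes_test": self.fold_sizes_test,
            "train_metrics": [m.to_dict() for m in self.train_metrics],
            "test_metrics": [m.to_dict() for m in self.test_metrics],
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "cumulative_train_accuracy": self.cumulative_train_accuracy,
            "cumulative_test_accuracy": self.cumulative_test_accuracy,
            "train_confusion": {
                "labels": list(self.train_confusion.index),
                "matrix": self.train_confusion.to_numpy().tolist(),
            },
            "test_confusion": {
                "labels": list(self.test_confusion.index),
                "matrix": self.test_confusion.to_numpy().tolist(),
            },
            "jaw_correct_rate": self.jaw_correct_rate,
            "neighbor_or_correct_rate": self.neighbor_or_correct_rate,
            "n_selected_per_fold": self.n_selected_per_fold,
            "selected_names_per_fold": self.selected_names_per_fold,
            "config": self.config,
        }


def evaluate_features(X: np.ndarray, y: np.ndarray, config: RunConfig,
                      feature_names: list[str] | None = None) -> CVReport:
    """Cross-validate selection + GNB on an extracted feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = stratified_kfold(y, k=config.cv.k, seed=config.cv.seed)

    global_sel = None
    if config.selection.scope == "global":
        params_all = standardize_fit(X)
        imps = l2_importances(
            standardize_apply(X, params_all), y,
            C=config.selection.C, aggregation=config.selection.aggregation,
        )
        global_sel = select(imps, names=feature_names)

    fold_sizes_train: list[int] = []
    fold_sizes_test: list[int] = []
    train_metrics: list[Metrics] = []
    test_metrics: list[Metrics] = []
    train_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    test_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    n_selected: list[int] = []
    selected_names: list[list[str]] = []
    pooled_true: list = []
    pooled_pred: list = []

    for train_idx, test_idx in folds.split():
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        params = standardize_fit(X_tr)
        X_tr_std = standardize_apply(X_tr, params)
        X_te_std = standardize_apply(X_te, params)

        if global_sel is not None:
            sel = global_sel
        else:
            imps = l2_importances(
                X_tr_std, y_tr,
                C=config.selection.C, aggregation=config.selection.aggregation,
            )
            sel = select(imps, names=feature_names)
        mask = sel.mask
        n_selected.append(int(mask.sum()))
        selected_names.append(sel.selected_names if feature_names else [])

        label_order = [c for c in LABEL_CODES if c in set(map(str, y_tr))] or None
        model = gnb_fit(X_tr_std[:, mask], y_tr, labels=label_order)
        pred_tr = gnb_predict(model, X_tr_std[:, mask])
        pred_te = gnb_predict(model, X_te_std[:, mask])

        fold_sizes_train.append(len(train_idx))
        fold_sizes_test.append(len(test_idx))
        train_metrics.append(classification_metrics(y_tr, pred_tr))
        test_metrics.append(classification_metrics(y_te, pred_te))
        train_pairs.append((y_tr, pred_tr))
        test_pairs.append((y_te, pred_te))
        pooled_true.extend(y_te)
        pooled_pred.extend(pred_te)

    jaw_rate, near_rate = clinical_rates(pooled_true, pooled_pred)
    return CVReport(
        fold_sizes_train=fold_sizes_train,
        fold_sizes_test=fold_sizes_test,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        train_confusion=cumulative_confusion(train_pairs),
        test_confusion=cumulative_confusion(test_pairs),
        jaw_correct_rate=jaw_rate,
        neighbor_or_correct_rate=near_rate,
        n_selected_per_fold=n_selected,
        selected_names_per_fold=selected_names,
        config=config.to_dict(),
    )


def run_pipeline(recordings: list[RawRecording], config: RunConfig | None = None) -> CVReport:
    """End-to-end: preprocess, extract features, select, classify, report."""
    config = config if config is not None else RunConfig()
    if not recordings:
        raise ValueError("no recordings provided")
    catalogue = build_catalogue()
    processed = [preprocess(rec, config.preprocessing) for rec in recordings]
    df = feature_matrix(processed, catalogue, config.features)
    names = [d.name for d in catalogue]
    X = df[names].to_numpy()
    y = df["label"].to_numpy()
    return evaluate_features(X, y, config, feature_names=names)
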