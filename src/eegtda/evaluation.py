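"""Leave-one-subject-out random-forest classification and regression.

Each cross-validation fold holds out every epoch of one subject and
trains a 200-tree random forest on the six topological features of all
remaining subjects' epochs — the grouping guarantees that no information
from the held-out subject leaks into training. Classification targets
the healthy/MCI label, regression the integer MoCA score; both are
scored at epoch level, with metric panels aggregated as the median and
2.5-97.5 percentile interval across folds plus pooled values over all
held-out predictions.

The chance level of an unbalanced study is the majority-class
proportion (e.g. 16 MCI of 23 subjects -> 70%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_auc_score)

from .tda import FEATURE_NAMES

__all__ = ["FoldResult", "MetricPanel", "loso_folds", "classify_loso",
           "regress_loso", "chance_level", "metric_suite"]

POSITIVE_CLASS = "mci"


@dataclass
class FoldResult:
    held_out_subject: str
    true_label: str | None = None
    true_moca: float | None = None
    predicted_labels: np.ndarray | None = None
    scores: np.ndarray | None = None        # P(class = mci) per epoch
    predicted_moca: np.ndarray | None = None
    metrics: dict = field(default_factory=dict)


@dataclass
class MetricPanel:
    """Fold-median metrics with percentile intervals, plus pooled values."""

    median: dict
    interval: dict       # metric -> (2.5th, 97.5th percentile across folds)
    pooled: dict
    n_folds: int


def _subset(features: pd.DataFrame, condition: str) -> pd.DataFrame:
    if condition not in ("TGT", "IGN", "ALL"):
        raise ValueError(f"unknown condition {condition!r}")
    out = features if condition == "ALL" else \
        features[features["condition"] == condition]
    if len(out) == 0:
        raise ValueError(f"no epochs for condition {condition}")
    return out


def loso_folds(features: pd.DataFrame):
    """One (train_idx, test_idx) partition per subject (positional indices)."""
    subjects = features["subject_id"].to_numpy()
    unique = pd.unique(subjects)
    if len(unique) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subj in unique:
        test = np.nonzero(subjects == subj)[0]
        train = np.nonzero(subjects != subj)[0]
        assert subj not in set(subjects[train])  # no-leakage audit
        folds.append((train, test))
    return folds


def chance_level(subject_labels) -> int:
    """Majority-class proportion as an integer percent."""
    labels = pd.Series(list(subject_labels))
    if len(labels) == 0:
        raise ValueError("empty label list")
    top = labels.value_counts(normalize=True).iloc[0]
    return int(math.floor(top * 100 + 0.5))


def metric_suite(y_true, y_pred, scores=None, task: str = "classification",
                 average: str = "weighted") -> dict:
    """Standard metric panel for one prediction vector.

    Classification: accuracy (percent), auc (from ``scores``; NaN with a
    warning when only one class is present), f1/recall/precision
    (``average`` across classes; per-class values under ``*_mci`` /
    ``*_healthy``). Regression: r2, mse, mae, median_error, mape
    (percent).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if task == "regression":
        err = y_pred.astype(float) - y_true.astype(float)
        ss_res = float((err**2).sum())
        ss_tot = float(((y_true - y_true.mean())**2).sum())
        return {
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
            "mse": float((err**2).mean()),
            "mae": float(np.abs(err).mean()),
            "median_error": float(np.median(np.abs(err))),
            "mape": float(np.mean(np.abs(err) / np.abs(y_true)) * 100.0),
        }
    out = {"accuracy": float((y_true == y_pred).mean() * 100.0)}
    if scores is not None:
        if len(set(y_true)) < 2:
            warnings.warn("AUC undefined with a single true class; "
                          "reported as NaN", stacklevel=2)
            out["auc"] = float("nan")
        else:
            out["auc"] = float(roc_auc_score(
                (y_true == POSITIVE_CLASS).astype(int), scores))
    kw = dict(average=average, zero_division=0)
    out["f1"] = float(f1_score(y_true, y_pred, **kw))
    out["recall"] = float(recall_score(y_true, y_pred, **kw))
    out["precision"] = float(precision_score(y_true, y_pred, **kw))
    for cls in ("mci", "healthy"):
        pc = dict(labels=[cls], average=None, zero_division=0)
        if cls in set(y_true) or cls in set(y_pred):
            out[f"f1_{cls}"] = float(f1_score(y_true, y_pred, **pc)[0])
    return out


def _aggregate(fold_metrics: list, pooled: dict) -> MetricPanel:
    keys = sorted({k for m in fold_metrics for k in m})
    median, interval = {}, {}
    for k in keys:
        vals = np.array([m[k] for m in fold_metrics if k in m], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            median[k] = float("nan")
            interval[k] = (float("nan"), float("nan"))
        else:
            median[k] = float(np.median(vals))
            interval[k] = (float(np.percentile(vals, 2.5)),
                           float(np.percentile(vals, 97.5)))
    return MetricPanel(median=median, interval=interval, pooled=pooled,
                       n_folds=len(fold_metrics))


def classify_loso(features: pd.DataFrame, condition: str = "ALL",
                  n_trees: int = 200, seed: int = 0,
                  per_subject_vote: bool = False):
    """LOSO random-forest MCI classification; returns (panel, fold_results).

    With ``per_subject_vote`` the held-out subject's label is the
    majority vote over its epochs (one prediction per fold); otherwise
    every epoch is scored individually.
    """
    sub = _subset(features, condition).reset_index(drop=True)
    x = sub.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = sub["group"].to_numpy()
    subjects = sub["subject_id"].to_numpy()
    results, fold_metrics = [], []
    pooled_true, pooled_pred, pooled_score = [], [], []
    for train, test in loso_folds(sub):
        if len(set(y[train])) < 2:
            raise ValueError(
                "training fold contains a single class; the study needs "
                "both healthy and MCI subjects in every training set")
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(x[train], y[train])
        proba = clf.predict_proba(x[test])
        score = proba[:, list(clf.classes_).index(POSITIVE_CLASS)]
        pred = clf.predict(x[test])
        true_label = y[test][0]
        if per_subject_vote:
            vote = pd.Series(pred).mode().iloc[0]
            pred = np.full(len(pred), vote)
        m = metric_suite(y[test], pred)
        fr = FoldResult(held_out_subject=subjects[test][0],
                        true_label=true_label, predicted_labels=pred,
                        scores=score, metrics=m)
        results.append(fr)
        fold_metrics.append(m)
        pooled_true.extend(y[test])
        pooled_pred.extend(pred)
        pooled_score.extend(score)
    pooled = metric_suite(np.array(pooled_true), np.array(pooled_pred),
                          scores=np.array(pooled_score))
    return _aggregate(fold_metrics, pooled), results


def regress_loso(features: pd.DataFrame, condition: str = "ALL",
                 n_trees: int = 200, seed: int = 0):
    """LOSO random-forest MoCA regression; returns (panel, fold_results).

    r2/mse/mae/mape are pooled over all held-out epoch predictions (a
    single subject has one MoCA value, so per-fold r2 is degenerate);
    per-fold ``median_error`` is |median predicted - true| per subject.
    """
    sub = _subset(features, condition).reset_index(drop=True)
    x = sub.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = sub["moca"].to_numpy(dtype=float)
    subjects = sub["subject_id"].to_numpy()
    results, fold_metrics = [], []
    pooled_true, pooled_pred = [], []
    for train, test in loso_folds(sub):
        reg = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
        reg.fit(x[train], y[train])
        pred = reg.predict(x[test])
        true_moca = float(y[test][0])
        m = {
            "mae": float(np.abs(pred - y[test]).mean()),
            "mse": float(((pred - y[test])**2).mean()),
            "mape": float(np.mean(np.abs(pred - y[test]) / np.abs(y[test]))
                          * 100.0),
            "median_error": float(abs(np.median(pred) - true_moca)),
        }
        results.append(FoldResult(held_out_subject=subjects[test][0],
                                  true_moca=true_moca, predicted_moca=pred,
                                  metrics=m))
        fold_metrics.append(m)
        pooled_true.extend(y[test])
        pooled_pred.extend(pred)
    pooled = metric_suite(np.array(pooled_true), np.array(pooled_pred),
                          task="regression")
    return _aggregate(fold_metrics, pooled), results
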