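"""Classification evaluation by repeated stratified cross-validation.

Metrics are accuracy, sensitivity (TP/(TP+FN); the disease cohort is the
positive class), specificity (TN/(TN+FP)) and AUC.  AUC is the rank
statistic (probability a random positive outscores a random negative,
ties counted 1/2), computed threshold-free; the other metrics use a fixed
probability threshold of 0.5.  Folds preserve class counts, so with 20
positives and 10 folds every fold holds exactly 2 positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold

METRICS = ("accuracy", "sensitivity", "specificity", "auc")


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 0.5; NaN when one class absent."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-matrix metrics at ``threshold`` plus rank AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": sens,
        "specificity": spec,
        "auc": rank_auc(y_true, scores),
    }


@dataclass
class EvaluationReport:
    """Cross-validated metrics for one model on one dataset."""

    model_name: str
    n_folds: int
    n_repeats: int
    seed: int
    per_fold: pd.DataFrame  # one row per fold x repeat
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    roc_points: pd.DataFrame | None = None  # pooled fpr/tpr curve
    fold_positive_counts: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}).loc[list(METRICS)]


def _roc_points(y: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y)[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = tps / max(int((y == 1).sum()), 1)
    fpr = fps / max(int((y == 0).sum()), 1)
    return pd.DataFrame(
        {"fpr": np.concatenate([[0.0], fpr]), "tpr": np.concatenate([[0.0], tpr])}
    )


def repeated_stratified_cv(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[], object],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    model_name: str = "model",
    threshold: float = 0.5,
) -> EvaluationReport:
    """Repeated stratified k-fold CV with per-fold metrics and pooled ROC.

    ``model_factory`` returns a fresh estimator with ``fit(X, y)`` and
    ``predict_proba(X)`` (positive-class probability).  Each repeat uses a
    fresh stratified shuffle derived from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    smallest = min(int((y == 1).sum()), int((y == 0).sum()))
    if smallest < k:
        raise ValueError(
            f"smallest class has {smallest} samples < {k} folds; reduce k"
        )
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rows = []
    pooled_y, pooled_s = [], []
    pos_counts = []
    for fold_id, (tr, te) in enumerate(cv.split(X, y)):
        model = model_factory()
        model.fit(X[tr], y[tr])  # type: ignore[attr-defined]
        scores = np.asarray(model.predict_proba(X[te]), dtype=float)  # type: ignore[attr-defined]
        if scores.ndim == 2:  # sklearn-style (n, 2) probabilities
            scores = scores[:, 1]
        m = compute_metrics(y[te], scores, threshold)
        m["repeat"] = fold_id // k
        m["fold"] = fold_id % k
        rows.append(m)
        pooled_y.append(y[te])
        pooled_s.append(scores)
        pos_counts.append(int((y[te] == 1).sum()))
    per_fold = pd.DataFrame(rows)
    mean = {m: float(np.nanmean(per_fold[m])) for m in METRICS}
    sd = {m: float(np.nanstd(per_fold[m], ddof=1)) for m in METRICS}
    roc = _roc_points(np.concatenate(pooled_y), np.concatenate(pooled_s))
    return EvaluationReport(
        model_name, k, repeats, seed, per_fold, mean, sd, roc, pos_counts
    )


def compare_gene_sets(
    dataset_a: np.ndarray,
    dataset_b: np.ndarray,
    y: np.ndarray,
    model_factories: dict[str, Callable[[], object]],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, dict[str, EvaluationReport | dict[str, float]]]:
    """Evaluate two feature sets on the same samples with the same folds.

    ``dataset_a`` and ``dataset_b`` share rows (samples and labels); only
    the feature columns differ (e.g. proposed vs known gene sets).
    Returns per model the two reports plus paired metric deltas (A - B).
    """
    a, b = np.asarray(dataset_a, dtype=float), np.asarray(dataset_b, dtype=float)
    if a.shape[0] != b.shape[0] or a.shape[0] != len(y):
        raise ValueError("datasets must share samples and labels")
    out: dict[str, dict[str, EvaluationReport | dict[str, float]]] = {}
    for name, factory in model_factories.items():
        rep_a = repeated_stratified_cv(a, y, factory, k, repeats, seed, f"{name}[A]")
        rep_b = repeated_stratified_cv(b, y, factory, k, repeats, seed, f"{name}[B]")
        delta = {m: rep_a.mean[m] - rep_b.mean[m] for m in METRICS}
        out[name] = {"A": rep_a, "B": rep_b, "delta": delta}
    return out
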