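"""Decoding performance metrics: accuracy, one-vs-all ROC/AUC, PPV/recall/F1,
confusion matrices, and one-sample t-tests against chance with Bonferroni
control.

Undefined ratios (e.g. PPV with no positive predictions) are missing-coded
as NaN rather than forced to zero, and a class absent from the labels gets
a NaN AUC that is excluded from the macro average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _confusion_matrix
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "MetricsReport",
    "compute_accuracy",
    "roc_ovr",
    "binary_prf",
    "ttest_vs_chance",
    "metrics_report",
]

#: FPR grid for vertical averaging of per-class ROC curves.
FPR_GRID = np.linspace(0.0, 1.0, 101)


def compute_accuracy(predictions, labels) -> float:
    """Proportion of correct predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be nonempty and equal-length")
    return float(np.mean(predictions == labels))


def roc_ovr(scores: np.ndarray, labels, classes=None):
    """One-vs-all ROC analysis of multiclass scores.

    Each class is treated as a binary problem against the rest using its
    score column; AUCs are trapezoidal.  The macro curve averages the
    per-class TPR vertically on a common 101-point FPR grid, and the macro
    AUC is the mean of per-class AUCs (NaN-coded classes excluded).

    Returns ``(curves, macro_curve, aucs)`` where ``curves`` maps class ->
    (fpr, tpr), ``macro_curve`` is (FPR_GRID, mean_tpr), and ``aucs`` is
    aligned with ``classes``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n_trials, n_classes)")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    curves: dict = {}
    aucs = np.full(len(classes), np.nan)
    tprs = []
    for k, cls in enumerate(classes):
        pos = labels == cls
        if pos.all() or not pos.any():
            continue  # class absent (or alone): AUC missing-coded
        fpr, tpr, _ = _roc_curve(pos.astype(int), scores[:, k])
        curves[cls] = (fpr, tpr)
        aucs[k] = _auc(fpr, tpr)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    macro_curve = (FPR_GRID, np.mean(tprs, axis=0) if tprs else np.full_like(FPR_GRID, np.nan))
    return curves, macro_curve, aucs


def binary_prf(predictions, labels, positive_class):
    """PPV, recall and F1 for a binary problem.

    Zero-denominator cases are missing-coded as NaN (the convention used
    for undefined precision when a class is never predicted).
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(np.unique(labels)) > 2:
        raise ValueError("binary_prf requires binary labels")
    tp = float(np.sum((predictions == positive_class) & (labels == positive_class)))
    fp = float(np.sum((predictions == positive_class) & (labels != positive_class)))
    fn = float(np.sum((predictions != positive_class) & (labels == positive_class)))
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if np.isnan(ppv) or np.isnan(recall) or ppv + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * recall / (ppv + recall)
    return ppv, recall, f1


def ttest_vs_chance(values, chance: float, n_tests: int = 1, fwer: float = 0.05):
    """Two-sided one-sample t-test of per-subject metric values vs. chance.

    Bonferroni control: the per-test alpha is ``fwer / n_tests`` (e.g.
    0.05 / 4 = 0.0125).  Zero variance across subjects gives a NaN p-value
    and a non-significant decision.

    Returns ``(p_value, alpha_per_test, significant)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(values).all():
        raise ValueError("metric values must be finite")
    alpha = fwer / n_tests
    if values.std() == 0:
        return float("nan"), alpha, False
    p = float(stats.ttest_1samp(values, chance).pvalue)
    return p, alpha, p < alpha


@dataclass
class MetricsReport:
    """Aggregate report over one evaluation (typically pooled subjects)."""

    accuracy: float
    per_subject_accuracy: dict
    classes: np.ndarray
    chance: float
    auc_per_class: np.ndarray
    macro_auc: float
    roc_curves: dict
    macro_curve: tuple
    confusion: np.ndarray
    p_value: float = float("nan")
    alpha: float = float("nan")
    significant: bool = False
    ppv: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")


def metrics_report(results, n_tests: int = 4, fwer: float = 0.05) -> MetricsReport:
    """Build a full report from per-subject EvalResults.

    ``results`` is a dict subject -> EvalResult (or a single EvalResult).
    Trials are pooled for ROC/confusion; per-subject accuracies feed the
    chance-level t-test.  For binary problems PPV/recall/F1 use the second
    class (in class order) as the positive one.
    """
    if not isinstance(results, dict):
        results = {"all": results}
    per_subj = {s: r.accuracy for s, r in results.items()}
    first = next(iter(results.values()))
    classes = first.classes
    labels = np.concatenate([r.labels for r in results.values()])
    preds = np.concatenate([r.predictions for r in results.values()])
    scores = np.concatenate([r.scores for r in results.values()])
    curves, macro_curve, aucs = roc_ovr(scores, labels, classes=classes)
    chance = 1.0 / len(classes)
    acc = compute_accuracy(preds, labels)
    if len(per_subj) >= 2:
        p, alpha, sig = ttest_vs_chance(list(per_subj.values()), chance, n_tests, fwer)
    else:
        p, alpha, sig = float("nan"), fwer / n_tests, False
    rep = MetricsReport(
        accuracy=acc,
        per_subject_accuracy=per_subj,
        classes=classes,
        chance=chance,
        auc_per_class=aucs,
        macro_auc=float(np.nanmean(aucs)) if np.isfinite(aucs).any() else float("nan"),
        roc_curves=curves,
        macro_curve=macro_curve,
        confusion=_confusion_matrix(labels, preds, labels=classes),
        p_value=p,
        alpha=alpha,
        significant=sig,
    )
    if len(classes) == 2:
        rep.ppv, rep.recall, rep.f1 = binary_prf(preds, labels, classes[1])
    return rep
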