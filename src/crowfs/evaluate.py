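"""Final evaluation of a selected feature subset.

A selected mask is graded by a support-vector machine with a radial-basis
kernel at a fixed, deliberately small penalty (C = 0.1, controlling
overfitting and keeping the comparison consistent across masks).  The kernel
width follows the data-driven rule gamma = 1 / (d * pooled variance) with
``d`` the selected feature count (sklearn's ``gamma="scale"``); multiclass
decisions use one-vs-rest decision scores.

The report carries the confusion matrix, per-class TP/FP/TN/FN, accuracy,
per-class and averaged precision/recall/F1 (headline averaging is
support-weighted; macro also reported), and one-vs-rest PR and ROC curves
with their areas (trapezoidal AUROC; step-wise average precision for the PR
area), macro-averaged across classes by default with micro selectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (auc, average_precision_score, confusion_matrix,
                             precision_recall_curve, roc_curve)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import FeatureMatrix, apply_zscore, fit_zscore

__all__ = ["EvaluationReport", "train_svm_rbf", "compute_metrics", "curves",
           "evaluate_selection", "plot_curves"]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Confusion counts, per-class and averaged metrics, and curve data."""

    classes: list[int] = field(default_factory=list)
    confusion: np.ndarray | None = None          # rows = true class
    tp: np.ndarray | None = None
    fp: np.ndarray | None = None
    tn: np.ndarray | None = None
    fn: np.ndarray | None = None
    support: np.ndarray | None = None
    accuracy: float = 0.0
    precision: np.ndarray | None = None          # per class
    recall: np.ndarray | None = None
    f1: np.ndarray | None = None
    weighted: dict = field(default_factory=dict)  # precision/recall/f1
    macro: dict = field(default_factory=dict)
    roc_curves: dict = field(default_factory=dict)   # class -> {fpr,tpr,auc}
    pr_curves: dict = field(default_factory=dict)    # class -> {rec,prec,ap}
    auroc_macro: float | None = None
    aupr_macro: float | None = None
    auroc_micro: float | None = None
    aupr_micro: float | None = None
    cv_auroc_macro: float | None = None
    cv_aupr_macro: float | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "classes": list(map(int, self.classes)),
            "confusion": arr(self.confusion),
            "tp": arr(self.tp), "fp": arr(self.fp),
            "tn": arr(self.tn), "fn": arr(self.fn),
            "support": arr(self.support),
            "accuracy": self.accuracy,
            "precision": arr(self.precision),
            "recall": arr(self.recall),
            "f1": arr(self.f1),
            "weighted": self.weighted,
            "macro": self.macro,
            "roc_curves": {str(c): {k: arr(v) for k, v in d.items()}
                           for c, d in self.roc_curves.items()},
            "pr_curves": {str(c): {k: arr(v) for k, v in d.items()}
                          for c, d in self.pr_curves.items()},
            "auroc_macro": self.auroc_macro,
            "aupr_macro": self.aupr_macro,
            "auroc_micro": self.auroc_micro,
            "aupr_micro": self.aupr_micro,
            "cv_auroc_macro": self.cv_auroc_macro,
            "cv_aupr_macro": self.cv_aupr_macro,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def train_svm_rbf(train: FeatureMatrix, mask, penalty: float = 0.1,
                  seed: int = 0) -> SVC:
    """Fit an RBF-kernel SVM on the masked columns of (normalized) training
    data; one-vs-rest decision scores, gamma = 1/(d * pooled variance)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no features")
    if train.n_classes < 2:
        raise ValueError("training data has a single class")
    model = SVC(C=penalty, kernel="rbf", gamma="scale",
                decision_function_shape="ovr", random_state=seed)
    model.fit(train.values[:, mask], train.labels)
    return model


def compute_metrics(y_true, y_pred, classes=None) -> EvaluationReport:
    """One-vs-rest TP/FP/TN/FN per class and the derived metric family.

    Weighted averages weight by true-class support; F1 is 0 where precision
    and recall are both 0."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("truth and prediction must be equal-length, non-empty")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(classes)
        if not np.isin(y_pred, classes).all() or not np.isin(y_true, classes).all():
            raise ValueError("label outside the declared classes")
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    support = cm.sum(axis=1).astype(float)
    wts = support / support.sum()
    report = EvaluationReport(
        classes=list(map(int, classes)),
        confusion=cm, tp=tp, fp=fp, tn=tn, fn=fn, support=support,
        accuracy=float(tp.sum() / total),
        precision=precision, recall=recall, f1=f1,
        weighted={"precision": float(precision @ wts),
                  "recall": float(recall @ wts),
                  "f1": float(f1 @ wts)},
        macro={"precision": float(precision.mean()),
               "recall": float(recall.mean()),
               "f1": float(f1.mean())},
    )
    return report


def curves(y_true, scores, classes=None,
           report: EvaluationReport | None = None) -> EvaluationReport:
    """One-vs-rest PR and ROC curves with areas, per class and averaged.

    ``scores`` is an ``(n, K)`` array of decision values, one column per
    class.  Classes absent from the truth are skipped (logged).  Macro
    averages are unweighted means over the evaluated classes; micro averages
    pool all (sample, class) decisions."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if scores.shape != (y_true.size, classes.size):
        raise ValueError("scores shape must match (n_samples, n_classes)")
    if report is None:
        report = EvaluationReport(classes=list(map(int, classes)))
    aurocs, auprs = [], []
    onehot = (y_true[:, None] == classes[None, :]).astype(int)
    kept = np.zeros(classes.size, dtype=bool)
    for idx, c in enumerate(classes):
        pos = onehot[:, idx]
        if pos.sum() == 0 or pos.sum() == pos.size:
            logger.info("class %s absent (or exhaustive) in truth; "
                        "skipped in curve averaging", c)
            continue
        kept[idx] = True
        fpr, tpr, _ = roc_curve(pos, scores[:, idx])
        area = float(auc(fpr, tpr))
        report.roc_curves[int(c)] = {"fpr": fpr, "tpr": tpr, "auc": area}
        aurocs.append(area)
        prec, rec, _ = precision_recall_curve(pos, scores[:, idx])
        ap = float(average_precision_score(pos, scores[:, idx]))
        report.pr_curves[int(c)] = {"recall": rec, "precision": prec,
                                    "ap": ap}
        auprs.append(ap)
    if aurocs:
        report.auroc_macro = float(np.mean(aurocs))
        report.aupr_macro = float(np.mean(auprs))
        flat_truth = onehot[:, kept].ravel()
        flat_score = scores[:, kept].ravel()
        fpr, tpr, _ = roc_curve(flat_truth, flat_score)
        report.auroc_micro = float(auc(fpr, tpr))
        report.aupr_micro = float(average_precision_score(flat_truth,
                                                          flat_score))
    return report


def _decision_scores(model: SVC, X: np.ndarray, n_classes: int) -> np.ndarray:
    s = model.decision_function(X)
    if s.ndim == 1:  # binary: one margin -> two signed columns
        s = np.column_stack([-s, s])
    return s


def evaluate_selection(train: FeatureMatrix, test: FeatureMatrix, mask,
                       penalty: float = 0.1, seed: int = 0,
                       cv_folds: int = 10) -> EvaluationReport:
    """Full held-out evaluation of a mask.

    Normalization is fit on the training split only and applied to both
    splits; the SVM is trained on the masked training columns and graded on
    the test split.  A cross-validated curve variant (stratified
    ``cv_folds``-fold on the training split, folds reduced for tiny classes)
    supplies ``cv_auroc_macro``/``cv_aupr_macro``."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test tables have different schemas")
    mask = np.asarray(mask, dtype=bool)
    norm = fit_zscore(train)
    train_z = apply_zscore(norm, train)
    test_z = apply_zscore(norm, test)
    classes = np.unique(train_z.labels)

    model = train_svm_rbf(train_z, mask, penalty=penalty, seed=seed)
    y_pred = model.predict(test_z.values[:, mask])
    report = compute_metrics(test_z.labels, y_pred, classes=classes)
    scores = _decision_scores(model, test_z.values[:, mask], classes.size)
    curves(test_z.labels, scores, classes=classes, report=report)

    # cross-validated curve averaging on the training split
    n_folds = min(cv_folds, int(np.bincount(train_z.labels).min()))
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        cv_scores = np.zeros((train_z.n_samples, classes.size))
        for tr, te in skf.split(train_z.values, train_z.labels):
            sub = FeatureMatrix(values=train_z.values[tr],
                                labels=train_z.labels[tr],
                                feature_names=list(train_z.feature_names))
            m = train_svm_rbf(sub, mask, penalty=penalty, seed=seed)
            raw = _decision_scores(m, train_z.values[np.ix_(te, np.flatnonzero(mask))],
                                   classes.size)
            if raw.shape[1] != classes.size:  # a fold may miss a class
                cols = {int(c): k for k, c in enumerate(m.classes_)}
                full = np.full((raw.shape[0], classes.size), -np.inf)
                for k, c in enumerate(classes):
                    if int(c) in cols:
                        full[:, k] = raw[:, cols[int(c)]]
                raw = full
            cv_scores[te] = raw
        cv_report = curves(train_z.labels, cv_scores, classes=classes)
        report.cv_auroc_macro = cv_report.auroc_macro
        report.cv_aupr_macro = cv_report.aupr_macro
    else:
        logger.info("skipping CV curve averaging: smallest class too small")
    return report


def plot_curves(report: EvaluationReport, path) -> None:
    """Write a two-panel PR / ROC figure for the per-class curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_pr, ax_roc) = plt.subplots(1, 2, figsize=(10, 4))
    for c, d in report.pr_curves.items():
        ax_pr.plot(d["recall"], d["precision"],
                   label=f"class {c} (AP={d['ap']:.3f})")
    ax_pr.set_xlabel("recall")
    ax_pr.set_ylabel("precision")
    ax_pr.set_title("PR curves")
    ax_pr.legend(fontsize=7)
    for c, d in report.roc_curves.items():
        ax_roc.plot(d["fpr"], d["tpr"],
                    label=f"class {c} (AUC={d['auc']:.3f})")
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax_roc.set_xlabel("false positive rate")
    ax_roc.set_ylabel("true positive rate")
    ax_roc.set_title("ROC curves")
    ax_roc.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
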