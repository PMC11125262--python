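"""Classification metrics: confusion matrix, accuracy, Cohen's kappa,
one-vs-rest precision/recall/F1 counts, and ROC/AUC.

Kappa is computed as (Po - Pe) / (1 - Pe) where Po is the observed accuracy
and Pe the chance agreement from the confusion-matrix marginals.  Per-class
metrics come from one-vs-rest TP/TN/FP/FN counts.  ROC curves are
one-vs-rest (scikit-learn's curve construction) with AUC by trapezoidal
integration, macro-averaged across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .errors import ConfigurationError


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """N x N count matrix, rows = true class, columns = predicted (1..N)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ConfigurationError("confusion matrix must be square")
    total = cm.sum()
    if total <= 0 or (cm < 0).any():
        raise ConfigurationError("confusion matrix must be non-negative "
                                 "with positive total")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if pe >= 1.0:
        raise ConfigurationError(
            "chance agreement Pe = 1 (degenerate single-cell matrix); "
            "kappa undefined")
    return float((po - pe) / (1.0 - pe))


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived rates for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def per_class_metrics(confusion: np.ndarray):
    cm = np.asarray(confusion)
    total = cm.sum()
    out = []
    for k in range(cm.shape[0]):
        tp = int(cm[k, k])
        fp = int(cm[:, k].sum() - tp)
        fn = int(cm[k, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        out.append(ClassMetrics(tp=tp, tn=tn, fp=fp, fn=fn))
    return out


def roc_auc_ovr(y_true, scores, n_classes: int):
    """One-vs-rest ROC points and trapezoidal AUC per class.

    ``scores`` is (trials, N); returns (list of (fpr, tpr, auc), macro AUC).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    curves, aucs = [], []
    for k in range(n_classes):
        binary = (y_true == k + 1).astype(int)
        if binary.min() == binary.max():
            # class absent (or exclusive) in the test set: AUC undefined
            curves.append((np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.nan))
            continue
        fpr, tpr, _ = roc_curve(binary, scores[:, k])
        auc = float(np.trapezoid(tpr, fpr))
        curves.append((fpr, tpr, auc))
        aucs.append(auc)
    macro = float(np.mean(aucs)) if aucs else float("nan")
    return curves, macro


@dataclass
class EvaluationReport:
    """Everything the metric suite derives from a set of predictions."""

    confusion: np.ndarray
    accuracy: float
    kappa: float
    po: float
    pe: float
    per_class: list = field(default_factory=list)
    roc: list = field(default_factory=list)      # (fpr, tpr, auc) per class
    macro_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "po": self.po,
            "pe": self.pe,
            "per_class": [
                {"tp": m.tp, "tn": m.tn, "fp": m.fp, "fn": m.fn,
                 "precision": m.precision, "recall": m.recall, "f1": m.f1}
                for m in self.per_class
            ],
            "auc_per_class": [c[2] for c in self.roc],
            "macro_auc": self.macro_auc,
        }


def report_from_predictions(y_true, y_pred, scores,
                            n_classes: int) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) == 0:
        raise ConfigurationError("empty test set")
    cm = confusion_matrix(y_true, y_pred, n_classes)
    total = cm.sum()
    po = float(np.trace(cm)) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    kappa = cohen_kappa(cm) if pe < 1.0 else float("nan")
    roc, macro = roc_auc_ovr(y_true, scores, n_classes) if scores is not None \
        else ([], float("nan"))
    return EvaluationReport(
        confusion=cm, accuracy=po, kappa=kappa, po=po, pe=pe,
        per_class=per_class_metrics(cm), roc=roc, macro_auc=macro)


def evaluate(model, X_test, y_test) -> EvaluationReport:
    """Run a trained model on a test set and populate the full report."""
    X_test = np.asarray(X_test)
    y_test = np.asarray(y_test, dtype=int)
    if len(X_test) == 0:
        raise ConfigurationError("empty test set")
    scores = model.predict_proba(X_test)
    y_pred = scores.argmax(axis=1) + 1
    return report_from_predictions(y_test, y_pred, scores, scores.shape[1])
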