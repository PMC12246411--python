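"""Classifier evaluation: confusion matrix, per-class and macro metrics,
one-vs-rest ROC curves and AUC.

Per class c (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), G-measure = sqrt(P*R) (the geometric mean), with the
zero-division convention metric = 0 (flagged).  Macro averages are
unweighted means over classes; accuracy is trace/total.  ROC curves are
per-class one-vs-rest with trapezoidal AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion, roc_curve as _sk_roc

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc",
    "evaluation_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray     # (K, K) ints; rows true, cols predicted
    labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    labels: list
    precision: dict
    recall: dict
    f1: dict
    g_measure: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_g_measure: float
    accuracy: float
    degenerate_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(c): {"precision": self.precision[c], "recall": self.recall[c],
                         "f1": self.f1[c], "g_measure": self.g_measure[c]}
                for c in self.labels},
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1, "g_measure": self.macro_g_measure},
            "accuracy": self.accuracy,
            "degenerate_classes": [str(c) for c in self.degenerate_classes],
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    positive_class: object = None


def confusion_matrix(y_true, y_pred, vocabulary: list) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true label i predicted as j."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    vocab_set = set(vocabulary)
    unknown = [v for v in set(y_true) | set(y_pred) if v not in vocab_set]
    if unknown:
        raise ValueError(f"labels not in vocabulary: {sorted(map(str, unknown))}")
    counts = _sk_confusion(y_true, y_pred, labels=list(vocabulary))
    return ConfusionMatrix(counts=counts, labels=list(vocabulary))


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro precision/recall/F1/G-measure plus accuracy."""
    counts = np.asarray(cm.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    def safe(num, den):
        return float(num / den) if den > 0 else 0.0

    precision, recall, f1, g = {}, {}, {}, {}
    degenerate = []
    for i, c in enumerate(cm.labels):
        p = safe(tp[i], tp[i] + fp[i])
        r = safe(tp[i], tp[i] + fn[i])
        precision[c], recall[c] = p, r
        f1[c] = safe(2.0 * p * r, p + r)
        g[c] = float(np.sqrt(p * r))
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            degenerate.append(c)
    vals = lambda d: np.array([d[c] for c in cm.labels])
    return MetricsReport(
        labels=list(cm.labels),
        precision=precision, recall=recall, f1=f1, g_measure=g,
        macro_precision=float(vals(precision).mean()),
        macro_recall=float(vals(recall).mean()),
        macro_f1=float(vals(f1).mean()),
        macro_g_measure=float(vals(g).mean()),
        accuracy=float(np.trace(counts) / counts.sum()),
        degenerate_classes=degenerate)


def roc_auc(y_true, scores: np.ndarray, positive_class, vocabulary: list) -> ROCCurve:
    """One-vs-rest ROC curve and trapezoidal AUC for one class.

    ``scores`` is the (n, K) per-class probability array with columns
    ordered as ``vocabulary``; ties between equal scores are grouped.
    """
    y_true = np.asarray(list(y_true))
    scores = np.asarray(scores, dtype=float)
    col = list(vocabulary).index(positive_class)
    pos = (y_true == positive_class).astype(int)
    if pos.sum() == 0 or pos.sum() == len(pos):
        raise ValueError(
            f"class {positive_class!r} needs both positives and negatives")
    fpr, tpr, thr = _sk_roc(pos, scores[:, col])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                    positive_class=positive_class)


def evaluation_report(y_true, probs: np.ndarray, vocabulary: list,
                      out_dir: str | Path | None = None) -> dict:
    """Everything at once: confusion matrix, metrics, per-class ROC/AUC.

    ``probs`` are per-sample class probability rows (columns ordered as
    ``vocabulary``); predictions are the row argmax.  When ``out_dir``
    is given the report is serialized as JSON plus flat CSV tables.
    """
    y_true = list(y_true)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    probs = np.asarray(probs, dtype=float)
    vocab = list(vocabulary)
    y_pred = [vocab[i] for i in probs.argmax(axis=1)]
    cm = confusion_matrix(y_true, y_pred, vocab)
    metrics = classification_metrics(cm)
    rocs = {}
    for c in vocab:
        try:
            rocs[c] = roc_auc(y_true, probs, c, vocab)
        except ValueError:
            rocs[c] = None
    report = {
        "confusion_matrix": {"labels": [str(c) for c in vocab],
                             "counts": cm.counts.tolist()},
        "metrics": metrics.to_dict(),
        "auc": {str(c): (None if r is None else r.auc) for c, r in rocs.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        lines = ["class,precision,recall,f1,g_measure,auc"]
        for c in vocab:
            a = report["auc"][str(c)]
            lines.append(",".join([
                str(c),
                f"{metrics.precision[c]:.6f}", f"{metrics.recall[c]:.6f}",
                f"{metrics.f1[c]:.6f}", f"{metrics.g_measure[c]:.6f}",
                "" if a is None else f"{a:.6f}"]))
        (out / "metrics.csv").write_text("\n".join(lines) + "\n")
        roc_lines = ["class,fpr,tpr,threshold"]
        for c, r in rocs.items():
            if r is None:
                continue
            for f, t, th in zip(r.fpr, r.tpr, r.thresholds):
                roc_lines.append(f"{c},{f:.6f},{t:.6f},{th:.6g}")
        (out / "roc_curves.csv").write_text("\n".join(roc_lines) + "\n")
    return report
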