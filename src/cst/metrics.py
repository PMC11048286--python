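"""Classification metric suite: confusion counts, accuracy, precision,
recall, F1 and ROC-AUC, with one-vs-rest treatment for multiclass problems.

Formulas (per one-vs-rest slice): accuracy = (TP+TN)/(TP+TN+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); the ROC curve
sweeps the decision threshold and plots TPR = TP/(TP+FN) against
FPR = FP/(FP+TN), whose area is the AUC (1 = perfect separation, 0.5 =
chance).  Multiclass scores are macro-averaged (unweighted mean over
classes) with per-class values retained.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .exceptions import DataError

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass
class MetricsReport:
    """Confusion-matrix counts and the derived metric suite.

    ``tp/tn/fp/fn`` are per-class one-vs-rest counts (index = class);
    ``precision/recall/f1`` are macro averages for multiclass input and the
    positive-class (class 1) values for binary input.  ``roc_auc`` is None
    when the labels contain a single class (the curve is undefined there).
    """

    confusion_matrix: np.ndarray
    class_names: List[str]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: Optional[float]
    per_class: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.confusion_matrix.sum())

    def to_dict(self) -> Dict[str, float]:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1}
        d["roc_auc"] = self.roc_auc if self.roc_auc is not None else float("nan")
        return d

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("metric      value\n")
        for k, v in self.to_dict().items():
            buf.write(f"{k:<10} {v:7.4f}\n")
        buf.write("\nconfusion matrix (rows = true class):\n")
        for name, row in zip(self.class_names, self.confusion_matrix):
            buf.write(f"{name:<12} " + " ".join(f"{int(v):6d}" for v in row)
                      + "\n")
        return buf.getvalue()


def _as_probabilities(scores: np.ndarray) -> np.ndarray:
    """Interpret scores as probabilities, applying softmax to logits."""
    rows = scores.sum(axis=1)
    if np.any(scores < 0) or not np.allclose(rows, 1.0, atol=1e-6):
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    return scores


def compute_metrics(y_true, scores, class_names: Optional[Sequence[str]] = None
                    ) -> MetricsReport:
    """Full metric report from labels and per-class scores.

    Parameters
    ----------
    y_true : int array [N]
    scores : array [N, n_classes]
        Per-class probabilities or logits (logits are softmaxed).
    """
    from sklearn.metrics import confusion_matrix as sk_confusion
    from sklearn.metrics import roc_auc_score

    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise DataError("scores must be [N, n_classes] matching y_true")
    n_classes = scores.shape[1]
    if len(y_true) and (y_true.min() < 0 or y_true.max() >= n_classes):
        raise DataError("labels outside [0, n_classes)")
    if class_names is None:
        class_names = [f"class{i}" for i in range(n_classes)]

    probs = _as_probabilities(scores)
    y_pred = probs.argmax(axis=1)
    cm = sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    total = cm.sum()

    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _safe(num, den):
        return float(num / den) if den > 0 else 0.0

    prec_c = np.array([_safe(tp[c], tp[c] + fp[c]) for c in range(n_classes)])
    rec_c = np.array([_safe(tp[c], tp[c] + fn[c]) for c in range(n_classes)])
    f1_c = np.array([
        _safe(2 * prec_c[c] * rec_c[c], prec_c[c] + rec_c[c])
        for c in range(n_classes)])

    # fraction correct (= (TP+TN)/N on the positive-class slice when binary)
    accuracy = _safe(tp.sum(), total)
    if n_classes == 2:
        precision, recall, f1 = prec_c[1], rec_c[1], f1_c[1]
    else:
        precision, recall, f1 = (float(prec_c.mean()), float(rec_c.mean()),
                                 float(f1_c.mean()))

    present = np.unique(y_true)
    if len(present) < 2:
        warnings.warn("ROC-AUC undefined: y_true contains a single class",
                      RuntimeWarning, stacklevel=2)
        roc_auc = None
    elif n_classes == 2:
        roc_auc = float(roc_auc_score(y_true, probs[:, 1]))
    else:
        if len(present) < n_classes:
            # macro one-vs-rest over the classes that are present
            aucs = []
            for c in present:
                aucs.append(roc_auc_score((y_true == c).astype(int),
                                          probs[:, c]))
            roc_auc = float(np.mean(aucs))
        else:
            roc_auc = float(roc_auc_score(y_true, probs, multi_class="ovr",
                                          average="macro"))

    per_class = {
        str(class_names[c]): {
            "precision": float(prec_c[c]),
            "recall": float(rec_c[c]),
            "f1": float(f1_c[c]),
            "support": int(cm[c].sum()),
        }
        for c in range(n_classes)
    }
    return MetricsReport(
        confusion_matrix=cm, class_names=[str(c) for c in class_names],
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=float(precision), recall=float(recall),
        f1=float(f1), roc_auc=roc_auc, per_class=per_class,
    )
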