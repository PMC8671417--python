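"""Classification metrics: confusion-matrix rates, mAUC, accuracy, F1.

Binary problems are summarised by the standard confusion-matrix derived
rates (sensitivity/TPR, specificity, precision/PPV, NPV, FPR, FDR, FNR,
accuracy, F1). Multiclass problems additionally use mAUC — the unweighted
mean of one-vs-rest ROC AUCs across classes — plus accuracy, balanced
accuracy (macro-averaged recall) and macro F1. Metrics with a zero
denominator are flagged undefined (None) rather than propagated as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_io import SampleLabels


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all-zero confusion counts")


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """All nine confusion-derived rates; zero-denominator entries are None."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, fp + tn),
        "precision": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "fpr": _ratio(fp, fp + tn),
        "fdr": _ratio(fp, fp + tp),
        "fnr": _ratio(fn, fn + tp),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
    }


def round_report(metrics: dict[str, float | None], decimals: int = 4) -> dict[str, float | None]:
    """Report-time rounding; internal values stay full precision."""
    return {k: (None if v is None else round(v, decimals)) for k, v in metrics.items()}


def mauc(scores: np.ndarray, labels: SampleLabels) -> float:
    """Unweighted mean of one-vs-rest ROC AUCs over classes.

    ``scores`` is (n_samples, n_classes) in class_set order. Classes absent
    from the labels are skipped with a warning.
    """
    y = np.array(labels.labels)
    present = [c for c in labels.class_set if (y == c).any()]
    skipped = [c for c in labels.class_set if c not in present]
    if skipped:
        warnings.warn(f"classes absent from labels skipped in mAUC: {skipped}")
    if len(present) < 2:
        raise ValueError("mAUC requires >= 2 classes present")
    aucs = []
    for c in present:
        k = labels.class_set.index(c)
        binary = (y == c).astype(int)
        if binary.all() or not binary.any():
            continue
        aucs.append(roc_auc_score(binary, scores[:, k]))
    return float(np.mean(aucs))


def summarize(
    predicted: list[str],
    scores: np.ndarray,
    labels: SampleLabels,
    positive_class: str | None = None,
) -> dict[str, float | None]:
    """Assemble the evaluation report for a prediction.

    For binary problems, F1 is computed on the designated positive class
    (default: the second class in class_set) and the confusion-derived rates
    are included; for k > 2, F1 is the unweighted (macro) average over
    classes. Accuracy is plain; balanced accuracy (macro recall) is reported
    alongside.
    """
    y = np.array(labels.labels)
    pred = np.array(predicted)
    if len(pred) != len(y):
        raise ValueError("prediction/label length mismatch")
    report: dict[str, float | None] = {}
    report["accuracy"] = float((pred == y).mean())
    recalls = []
    for c in labels.class_set:
        mask = y == c
        if mask.any():
            recalls.append(float((pred[mask] == c).mean()))
    report["balanced_accuracy"] = float(np.mean(recalls))
    report["mauc"] = mauc(scores, labels)
    if labels.n_classes == 2:
        pos = positive_class if positive_class is not None else labels.class_set[1]
        counts = ConfusionCounts(
            tp=int(((pred == pos) & (y == pos)).sum()),
            tn=int(((pred != pos) & (y != pos)).sum()),
            fp=int(((pred == pos) & (y != pos)).sum()),
            fn=int(((pred != pos) & (y == pos)).sum()),
        )
        report.update(confusion_metrics(counts))
    else:
        f1s = []
        for c in labels.class_set:
            tp = int(((pred == c) & (y == c)).sum())
            fp = int(((pred == c) & (y != c)).sum())
            fn = int(((pred != c) & (y == c)).sum())
            f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0)
        report["f1"] = float(np.mean(f1s))  # macro
    return report
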