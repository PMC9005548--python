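"""Multiclass agreement metrics: micro-F1, Cohen's kappa, balanced accuracy.

For single-label multiclass prediction the micro-averaged F1 score reduces
to the overall accuracy (total true positives over total cases). Cohen's
kappa corrects the observed agreement p_o for the chance agreement p_e
implied by the two marginal label distributions, kappa = (p_o - p_e) /
(1 - p_e). Balanced accuracy is the unweighted mean of per-class recalls;
classes with no true instance are excluded from the mean. A summary report
also carries the unweighted average of the three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricReport",
    "confusion_matrix",
    "micro_f1",
    "cohens_kappa",
    "balanced_accuracy",
    "evaluate",
]


def _validate(true: list, pred: list, class_set: list | None) -> tuple[list, list, list]:
    if len(true) != len(pred):
        raise ValueError("true and predicted label lists must have equal length")
    if not true:
        raise ValueError("label pairs must be non-empty")
    if class_set is None:
        class_set = list(dict.fromkeys(list(true) + list(pred)))
    known = set(class_set)
    for lab in list(true) + list(pred):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class set {class_set}")
    return list(true), list(pred), list(class_set)


def confusion_matrix(true: list, pred: list, class_set: list | None = None) -> np.ndarray:
    """Counts with entry (i, j) = cases of true class i predicted as class j."""
    true, pred, classes = _validate(true, pred, class_set)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true, pred):
        cm[index[t], index[p]] += 1
    return cm


def micro_f1(true: list, pred: list, class_set: list | None = None) -> float:
    """Overall accuracy: diagonal sum of the confusion matrix over total cases."""
    cm = confusion_matrix(true, pred, class_set)
    return float(np.trace(cm) / cm.sum())


def cohens_kappa(true: list, pred: list, class_set: list | None = None) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    cm = confusion_matrix(true, pred, class_set).astype(np.float64)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0  # degenerate single-class full agreement
        raise ArithmeticError("chance agreement 1 with observed agreement < 1")
    return float((p_o - p_e) / (1.0 - p_e))


def balanced_accuracy(true: list, pred: list, class_set: list | None = None) -> float:
    """Mean per-class recall over classes that occur in the truth."""
    cm = confusion_matrix(true, pred, class_set)
    truth_counts = cm.sum(axis=1)
    observed = truth_counts > 0
    recalls = cm.diagonal()[observed] / truth_counts[observed]
    return float(recalls.mean())


@dataclass(frozen=True)
class MetricReport:
    micro_f1: float
    kappa: float
    balanced_accuracy: float
    average: float
    confusion: np.ndarray
    class_set: tuple

    def as_dict(self) -> dict:
        return {
            "micro_f1": self.micro_f1,
            "kappa": self.kappa,
            "balanced_accuracy": self.balanced_accuracy,
            "average": self.average,
            "class_set": list(self.class_set),
            "confusion": self.confusion.tolist(),
        }


def evaluate(true: list, pred: list, class_set: list | None = None) -> MetricReport:
    """Compute all three agreement metrics plus their unweighted mean."""
    true, pred, classes = _validate(true, pred, class_set)
    f1 = micro_f1(true, pred, classes)
    kappa = cohens_kappa(true, pred, classes)
    bacc = balanced_accuracy(true, pred, classes)
    return MetricReport(
        micro_f1=f1,
        kappa=kappa,
        balanced_accuracy=bacc,
        average=(f1 + kappa + bacc) / 3.0,
        confusion=confusion_matrix(true, pred, classes),
        class_set=tuple(classes),
    )
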