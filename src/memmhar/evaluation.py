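"""Leave-one-subject-out cross-validation and classification metrics.

"Leave-one-out" is interpreted subject-wise: each fold holds out every
recording of one subject and trains on all other subjects, so no subject
appears on both sides of a fold.  Window-wise leave-one-out would leak
subject identity between train and test and overstate accuracy.

Mean accuracy is the unweighted mean of per-class recalls, i.e. the mean
of the diagonal of the row-normalized confusion matrix over populated
rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError


def loocv_folds(subject_ids):
    """One (train_subjects, test_subjects) pair per distinct subject.

    Subjects keep their order of first appearance; duplicated entries
    still yield one fold per distinct subject, and every subject tests
    exactly once.
    """
    seen = list(dict.fromkeys(str(s) for s in subject_ids))
    if len(seen) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in seen if s != test], [test]) for test in seen]


def confusion_matrix(true, pred, labels):
    """Row-normalized confusion matrix.

    Entry (i, j) is the fraction of class-``labels[i]`` windows predicted
    as ``labels[j]``.  Rows for classes with no true windows are all
    zero.  Raises on labels not covered by ``labels``.
    """
    true = np.atleast_1d(np.asarray(true, dtype=str))
    pred = np.atleast_1d(np.asarray(pred, dtype=str))
    if true.size != pred.size:
        raise ValueError("true and pred differ in length")
    if true.size == 0:
        raise EmptyInputError("no labels to score")
    labels = [str(lab) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for t, p in zip(true, pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normalized = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    return normalized


def mean_accuracy(confusion) -> float:
    """Unweighted mean of the diagonal over populated rows."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    populated = c.sum(axis=1) > 0
    if not populated.any():
        raise EmptyInputError("confusion matrix has no populated rows")
    return float(np.diag(c)[populated].mean())


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float
    #: True when a zero denominator forced a 0 entry.
    degenerate: bool = False

    def as_tuple(self):
        return (self.precision, self.recall, self.f_measure)


def precision_recall_f1(true, pred, labels) -> dict[str, ClassMetrics]:
    """Per-class precision, recall and F-measure.

    Zero denominators (a class never predicted, never present, or with
    P = R = 0) yield 0 with the ``degenerate`` flag set.
    """
    true = np.atleast_1d(np.asarray(true, dtype=str))
    pred = np.atleast_1d(np.asarray(pred, dtype=str))
    if true.size != pred.size:
        raise ValueError("true and pred differ in length")
    out = {}
    for lab in labels:
        lab = str(lab)
        tp = int(((true == lab) & (pred == lab)).sum())
        fp = int(((true != lab) & (pred == lab)).sum())
        fn = int(((true == lab) & (pred != lab)).sum())
        degenerate = False
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision, degenerate = 0.0, True
        if tp + fn > 0:
            recall = tp / (tp + fn)
        else:
            recall, degenerate = 0.0, True
        if precision + recall > 0:
            f_measure = 2 * precision * recall / (precision + recall)
        else:
            f_measure, degenerate = 0.0, True
        out[lab] = ClassMetrics(precision, recall, f_measure, degenerate)
    return out


@dataclass
class EvaluationReport:
    """Aggregated LOOCV results at window level."""

    labels: list[str]
    confusion: np.ndarray
    mean_accuracy: float
    per_class: dict[str, ClassMetrics]
    fold_assignments: dict[str, int] = field(default_factory=dict)
    n_windows: int = 0

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).tolist(),
            "mean_accuracy": self.mean_accuracy,
            "per_class": {
                lab: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "degenerate": m.degenerate,
                }
                for lab, m in self.per_class.items()
            },
            "fold_assignments": dict(self.fold_assignments),
            "n_windows": self.n_windows,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.labels,
                            columns=self.labels)

    def format_table(self) -> str:
        """Plain-text confusion table plus the mean accuracy line."""
        frame = self.confusion_frame().round(3)
        lines = [frame.to_string(), f"Mean accuracy = {self.mean_accuracy:.2%}"]
        return "\n".join(lines)


def evaluate_predictions(true, pred, labels, fold_assignments=None) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from pooled window labels."""
    confusion = confusion_matrix(true, pred, labels)
    return EvaluationReport(
        labels=[str(lab) for lab in labels],
        confusion=confusion,
        mean_accuracy=mean_accuracy(confusion),
        per_class=precision_recall_f1(true, pred, labels),
        fold_assignments=dict(fold_assignments or {}),
        n_windows=int(np.atleast_1d(np.asarray(true)).size),
    )
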