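"""Evaluation: confusion matrices, per-class F1, macro F1, Markov matrices.

The confusion matrix (rows = true stage, columns = predicted stage) is
reported raw and under both normalisations: dividing rows by the true-label
frequencies puts each class's **recall** on the diagonal; dividing columns
by the predicted-label frequencies puts **precision** there.  The F1 score
of a class is the harmonic mean of its precision and recall, and the summary
statistic is the unweighted mean of per-class F1 over the classes actually
present in the true labels.

Markov transition matrices count how often stage *i* is followed by stage
*j* between consecutive epochs (self-transitions included); transitions are
counted within each recording only, never across recording boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import AlignmentError, DataError
from .stages import REPORT_ORDER, Stage

__all__ = [
    "EvalReport",
    "confusion",
    "f1_from_pr",
    "macro_f1",
    "markov_matrix",
]


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


def f1_from_pr(precision, recall):
    """Harmonic mean of precision and recall; 0 where both are 0."""
    p = np.asarray(precision, dtype=np.float64)
    r = np.asarray(recall, dtype=np.float64)
    num, den = 2.0 * p * r, p + r
    result = np.divide(num, den, out=np.zeros_like(num), where=den != 0)
    return float(result) if result.ndim == 0 else result


def macro_f1(f1: np.ndarray, present: np.ndarray) -> float:
    """Unweighted mean F1 over classes present in the true labels."""
    present = np.asarray(present, dtype=bool)
    if not present.any():
        raise DataError("no classes present in the true labels")
    return float(np.mean(np.asarray(f1, dtype=np.float64)[present]))


@dataclass
class EvalReport:
    """Confusion statistics for one evaluated label set.

    Matrix rows/columns follow ``classes`` (stage codes).  ``f1`` is NaN for
    classes absent from the true labels; those classes are excluded from
    ``f1_mean``.
    """

    classes: np.ndarray
    cm_counts: np.ndarray
    cm_recall_norm: np.ndarray
    cm_precision_norm: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    f1_mean: float
    present: np.ndarray

    def per_class(self) -> pd.DataFrame:
        names = [Stage(c).name for c in self.classes]
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            index=names,
        )

    def save(self, out_dir) -> Path:
        """CSV matrices plus a JSON metrics summary."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = [Stage(c).name for c in self.classes]
        for mat, fname in [
            (self.cm_counts, "confusion_counts.csv"),
            (self.cm_recall_norm, "confusion_recall_norm.csv"),
            (self.cm_precision_norm, "confusion_precision_norm.csv"),
        ]:
            pd.DataFrame(mat, index=names, columns=names).to_csv(out_dir / fname)
        summary = {
            "f1_mean": round(self.f1_mean, 4),
            "per_class": {
                n: {
                    "precision": round(float(p), 4),
                    "recall": round(float(r), 4),
                    "f1": None if np.isnan(f) else round(float(f), 4),
                }
                for n, p, r, f in zip(names, self.precision, self.recall, self.f1)
            },
        }
        path = out_dir / "metrics.json"
        path.write_text(json.dumps(summary, indent=1) + "\n")
        return path


def _report_classes(y_true: np.ndarray, y_pred: np.ndarray,
                    classes) -> np.ndarray:
    if classes is not None:
        return np.asarray([int(c) for c in classes], dtype=np.int64)
    observed = set(np.unique(y_true)) | set(np.unique(y_pred))
    return np.asarray([int(s) for s in REPORT_ORDER if int(s) in observed],
                      dtype=np.int64)


def confusion(y_true, y_pred, classes=None) -> EvalReport:
    """Full confusion report for a pair of stage sequences.

    ``classes`` fixes the row/column order (stage codes); by default the
    observed stages in report order (Wake, REM, NREM, pre-REM, artifact).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise AlignmentError(
            f"{len(y_true)} true labels vs {len(y_pred)} predictions"
        )
    if len(y_true) == 0:
        raise DataError("cannot evaluate empty label sequences")
    cls = _report_classes(y_true, y_pred, classes)
    counts = _sk_confusion(y_true, y_pred, labels=cls)
    recall_norm = _safe_divide(counts, counts.sum(axis=1, keepdims=True))
    precision_norm = _safe_divide(counts, counts.sum(axis=0, keepdims=True))
    recall = np.diag(recall_norm)
    precision = np.diag(precision_norm)
    f1 = f1_from_pr(precision, recall)
    present = counts.sum(axis=1) > 0
    f1 = np.where(present, f1, np.nan)
    return EvalReport(
        classes=cls,
        cm_counts=counts,
        cm_recall_norm=recall_norm,
        cm_precision_norm=precision_norm,
        precision=precision,
        recall=recall,
        f1=f1,
        f1_mean=macro_f1(np.nan_to_num(f1), present),
        present=present,
    )


def markov_matrix(labels, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Transition counts and row-normalised probabilities.

    ``labels`` is one stage sequence or a list of sequences (one per
    recording; transitions never span recordings).  Returns
    ``(counts, row_normalised)`` over ``classes`` (default: observed stages
    in report order).
    """
    if isinstance(labels, (list, tuple)) and len(labels) and np.ndim(labels[0]) > 0:
        seqs = [np.asarray(s, dtype=np.int64) for s in labels]
    else:
        seqs = [np.asarray(labels, dtype=np.int64)]
    if sum(len(s) for s in seqs) == 0:
        raise DataError("cannot compute transitions of an empty sequence")
    merged = np.concatenate(seqs)
    cls = _report_classes(merged, merged, classes)
    pos = {int(c): i for i, c in enumerate(cls)}
    k = len(cls)
    counts = np.zeros((k, k), dtype=np.int64)
    for s in seqs:
        if len(s) < 2:
            continue
        i = np.array([pos[int(c)] for c in s[:-1]])
        j = np.array([pos[int(c)] for c in s[1:]])
        np.add.at(counts, (i, j), 1)
    return counts, _safe_divide(counts, counts.sum(axis=1, keepdims=True))
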