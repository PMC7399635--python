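"""Evaluation metrics: confusion counts, Sn/Sp/Acc/MCC and ROC/AUC.

Conventions: N+ and N- are the class totals; false_neg counts true sites
predicted as non-sites, false_pos counts non-sites predicted as sites.
Sn = 1 - false_neg/N+, Sp = 1 - false_pos/N-, Acc is the complement of the
overall error rate, and MCC is the Matthews correlation (the Pearson
correlation of the two binary vectors), defined as 0 when its denominator
vanishes.  AUC is the area under the ROC curve, equal to the Mann-Whitney
probability that a random positive outscores a random negative (ties 1/2).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import UndefinedMetricError, ValidationError


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation."""

    n_pos: int
    n_neg: int
    false_neg: int
    false_pos: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def _as_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def confusion_counts(
    labels: Sequence[int], predictions: Sequence[int]
) -> tuple[int, int, int, int]:
    """Return (N+, N-, false_neg, false_pos) for binary labels/predictions."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if len(y) != len(p):
        raise ValidationError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    false_neg = int(((y == 1) & (p == 0)).sum())
    false_pos = int(((y == 0) & (p == 1)).sum())
    return n_pos, n_neg, false_neg, false_pos


def compute_metrics(
    counts: tuple[int, int, int, int]
) -> tuple[float, float, float, float]:
    """Compute (Sn, Sp, Acc, MCC) from (N+, N-, false_neg, false_pos)."""
    n_pos, n_neg, false_neg, false_pos = counts
    if not (0 <= false_neg <= n_pos and 0 <= false_pos <= n_neg):
        raise ValidationError(f"inconsistent confusion counts: {counts}")
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("Sn/Sp require at least one sample of each class")
    sn = 1.0 - false_neg / n_pos
    sp = 1.0 - false_pos / n_neg
    acc = 1.0 - (false_neg + false_pos) / (n_pos + n_neg)
    tp = n_pos - false_neg
    tn = n_neg - false_pos
    denom = math.sqrt(
        float(tp + false_pos) * (tp + false_neg) * (tn + false_pos) * (tn + false_neg)
    )
    if denom == 0:
        warnings.warn("MCC denominator is zero; defining MCC = 0", RuntimeWarning)
        mcc = 0.0
    else:
        mcc = (tp * tn - false_pos * false_neg) / denom
    return sn, sp, acc, mcc


def make_report(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float] | None = None,
) -> EvalReport:
    """Build a full EvalReport; AUC is included when scores are given."""
    counts = confusion_counts(labels, predictions)
    sn, sp, acc, mcc = compute_metrics(counts)
    auc = roc_auc(labels, scores) if scores is not None else None
    return EvalReport(*counts, sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc)


def _check_roc_inputs(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValidationError(f"length mismatch: {len(y)} labels vs {len(s)} scores")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise UndefinedMetricError("ROC/AUC undefined: one class is absent")
    return y, s


def roc_curve_points(
    labels: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) at every distinct threshold, from (0,0) to (1,1)."""
    y, s = _check_roc_inputs(labels, scores)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve."""
    points = roc_curve_points(labels, scores)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def write_roc_tsv(points: list[tuple[float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr}\t{tpr}\n")
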