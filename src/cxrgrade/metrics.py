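"""Evaluation metrics for ordinal per-lung opacity grading.

The grading task is 4-class ordinal (grades 0-3), so the headline metric is
the macro-averaged mean absolute error: per-class MAE

    MAE_c = (1/n_c) * sum_{i: y_i = c} |y_i - yhat_i|

averaged without weights over the classes present in the truth vector.
Macro averaging keeps minority severity grades from being swamped by the
large clear/mild classes, while the absolute deviation penalizes an error
of two grades twice as hard as an error of one.

Precision, recall, and F1 are per-class one-vs-rest values combined as
support-weighted averages (weights n_c from the truth vector); undefined
per-class values from empty denominators are set to 0.  The coefficient of
determination R^2 treats grades as numeric scores.  Binary collapses fold
the four grades onto {below t, at or above t} for threshold t in {1, 2, 3}
(any-opacity, moderate-or-worse, severe).

Rates are stored as fractions; ``as_percent`` scales a report for display.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

__all__ = [
    "LabelPair",
    "MetricReport",
    "macro_mae",
    "weighted_prf",
    "r_squared",
    "binarize",
    "evaluate_pair",
    "BINARY_THRESHOLDS",
]

#: collapse thresholds: 1 = any opacity, 2 = moderate/severe, 3 = severe
BINARY_THRESHOLDS = (1, 2, 3)


@dataclasses.dataclass(frozen=True)
class LabelPair:
    """A matched pair of true and predicted ordinal grade vectors."""

    y_true: np.ndarray
    y_pred: np.ndarray
    n_classes: int = 4

    def __post_init__(self):
        yt = np.asarray(self.y_true, dtype=int)
        yp = np.asarray(self.y_pred, dtype=int)
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)
        if yt.shape != yp.shape or yt.ndim != 1:
            raise ValueError("y_true and y_pred must be 1-D and equal length")
        if yt.size < 1:
            raise ValueError("empty label pair")
        for v in (yt, yp):
            if v.min() < 0 or v.max() >= self.n_classes:
                raise ValueError(f"labels outside 0..{self.n_classes - 1}")

    def __len__(self) -> int:
        return self.y_true.size


@dataclasses.dataclass
class MetricReport:
    per_class_mae: dict
    macro_mae: float
    per_class_precision: dict
    per_class_recall: dict
    per_class_f1: dict
    support: dict
    precision_overall: float
    recall_overall: float
    f1_overall: float
    r_squared: float | None = None

    def as_percent(self) -> dict:
        """Rates scaled x100 for table display; MAE left on grade units."""
        return {
            "precision": 100 * self.precision_overall,
            "recall": 100 * self.recall_overall,
            "f1": 100 * self.f1_overall,
            "macro_mae": self.macro_mae,
            "r_squared": self.r_squared,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)


def macro_mae(pair: LabelPair, strict_k: bool = False) -> tuple[dict, float]:
    """Per-class MAE and its macro average.

    ``strict_k=True`` divides by the total class count K instead of the
    number of classes present in the truth vector.
    """
    yt, yp = pair.y_true, pair.y_pred
    per_class: dict[int, float] = {}
    for c in range(pair.n_classes):
        sel = yt == c
        if sel.any():
            per_class[c] = float(np.abs(yt[sel] - yp[sel]).mean())
    denom = pair.n_classes if strict_k else len(per_class)
    macro = float(sum(per_class.values()) / denom)
    return per_class, macro


def weighted_prf(pair: LabelPair) -> tuple[dict, dict, dict, float, float, float]:
    """Per-class precision/recall/F1 and their support-weighted averages."""
    yt, yp = pair.y_true, pair.y_pred
    precision, recall, f1, support = {}, {}, {}, {}
    for c in range(pair.n_classes):
        tp = int(((yt == c) & (yp == c)).sum())
        fp = int(((yt != c) & (yp == c)).sum())
        fn = int(((yt == c) & (yp != c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precision[c], recall[c], f1[c] = p, r, f
        support[c] = int((yt == c).sum())
    n = sum(support.values())
    pov = sum(precision[c] * support[c] for c in support) / n
    rov = sum(recall[c] * support[c] for c in support) / n
    fov = sum(f1[c] * support[c] for c in support) / n
    return precision, recall, f1, pov, rov, fov


def r_squared(pair: LabelPair) -> float:
    """Coefficient of determination with grades treated as numeric."""
    yt = pair.y_true.astype(float)
    yp = pair.y_pred.astype(float)
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero-variance truth")
    ss_res = float(((yt - yp) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def binarize(pair: LabelPair, threshold: int) -> LabelPair:
    """Collapse to a binary pair: 1 when grade >= threshold (t in 1..3)."""
    if threshold not in BINARY_THRESHOLDS:
        raise ValueError(f"threshold must be one of {BINARY_THRESHOLDS}")
    return LabelPair((pair.y_true >= threshold).astype(int),
                     (pair.y_pred >= threshold).astype(int), n_classes=2)


def evaluate_pair(y_true: Sequence, y_pred: Sequence, n_classes: int = 4,
                  strict_k: bool = False, with_r2: bool = True) -> MetricReport:
    """Full metric set for one truth/prediction pairing."""
    pair = LabelPair(np.asarray(y_true), np.asarray(y_pred), n_classes=n_classes)
    pc_mae, mmae = macro_mae(pair, strict_k=strict_k)
    prec, rec, f1, pov, rov, fov = weighted_prf(pair)
    r2 = None
    if with_r2:
        try:
            r2 = r_squared(pair)
        except ValueError:
            r2 = None
    support = {c: int((pair.y_true == c).sum()) for c in range(n_classes)}
    return MetricReport(pc_mae, mmae, prec, rec, f1, support, pov, rov, fov, r2)
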