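"""Confusion counting and the four benchmark statistics.

Networking is the positive class.  Sensitivity (SN), specificity (SP)
and overall accuracy (ACC) are reported in percent; Matthews'
correlation coefficient (MCC) in [-1, 1] (tables conventionally print
it as a percentage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import NETWORKING

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "mcc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(pred_labels: Sequence[int], true_labels: Sequence[int]) -> ConfusionCounts:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {true.shape} truths")
    p = pred == NETWORKING
    t = true == NETWORKING
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FN): percent of networking triads recovered."""
    if c.TP + c.FN == 0:
        raise ValueError("sensitivity undefined: no true networking samples")
    return 100.0 * c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """100 * TN / (TN + FP): percent of non-networking triads recovered."""
    if c.TN + c.FP == 0:
        raise ValueError("specificity undefined: no true non-networking samples")
    return 100.0 * c.TN / (c.TN + c.FP)


def accuracy(c: ConfusionCounts) -> float:
    """100 * (TP + TN) / total: overall percent correct."""
    if c.total == 0:
        raise ValueError("accuracy undefined on empty counts")
    return 100.0 * (c.TP + c.TN) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    denominator factor is zero the coefficient is defined as 0, with a
    warning (the usual convention for degenerate confusions).
    """
    factors = (c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN)
    if 0 in factors:
        warnings.warn("degenerate confusion counts: MCC defined as 0", stacklevel=2)
        return 0.0
    num = c.TP * c.TN - c.FP * c.FN
    return num / math.sqrt(math.prod(factors))
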