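"""Segmentation overlap metrics: Dice, recall, precision."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["OverlapScores", "dice", "recall_precision"]


@dataclass
class OverlapScores:
    dice: float
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int


def _check(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(A, B) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); two empty masks give 1."""
    A, B = _check(A, B)
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / denom


def recall_precision(pred, truth) -> OverlapScores:
    """Pixelwise recall/precision of ``pred`` against ``truth``.

    Precision is NaN for an empty prediction; recall is NaN for an empty
    truth mask.
    """
    pred, truth = _check(pred, truth)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    return OverlapScores(
        dice=dice(pred, truth), recall=recall, precision=precision, tp=tp, fp=fp, fn=fn
    )
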