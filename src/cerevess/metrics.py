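"""Voxel-overlap evaluation of a binary segmentation against a truth mask.

Counts A/B/C/D = true-positive/false-positive/true-negative/false-negative
voxels and derives

    DSC = 2A / (2A + B + D)      Sen = A / (A + D)
    PPV = A / (A + B)            Acc = (A + C) / (A + B + C + D)

A denominator of zero makes the corresponding score undefined; it is
reported as None (with a logged reason) rather than coerced to 0.  The
``literal_dsc`` flag reproduces the variant with true negatives in the
Dice denominator, 2A / (2A + C + D), for auditing only — it is not a
measure of overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["ConfusionCounts", "SegmentationScores", "confusion", "scores"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    A: int  # true positives
    B: int  # false positives
    C: int  # true negatives
    D: int  # false negatives

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class SegmentationScores:
    dsc: float | None
    sen: float | None
    ppv: float | None
    acc: float | None

    def as_dict(self) -> dict:
        return {"DSC": self.dsc, "Sen": self.sen, "PPV": self.ppv, "Acc": self.acc}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Joint-value voxel counts of a binary prediction vs. binary truth."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError(f"pred shape {p.shape} != truth shape {t.shape}")
    for name, arr in (("pred", p), ("truth", t)):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name}: labels must be binary {{0, 1}}")
    p = p.astype(bool)
    t = t.astype(bool)
    A = int(np.count_nonzero(p & t))
    B = int(np.count_nonzero(p & ~t))
    C = int(np.count_nonzero(~p & ~t))
    D = int(np.count_nonzero(~p & t))
    return ConfusionCounts(A, B, C, D)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return None
    return num / den


def scores(counts: ConfusionCounts, literal_dsc: bool = False) -> SegmentationScores:
    """DSC, Sen, PPV, Acc from confusion counts (None where undefined)."""
    if counts.total == 0:
        raise ValidationError("empty comparison: no voxels counted")
    A, B, C, D = counts.A, counts.B, counts.C, counts.D
    dsc_den = 2 * A + C + D if literal_dsc else 2 * A + B + D
    return SegmentationScores(
        dsc=_ratio(2 * A, dsc_den, "DSC"),
        sen=_ratio(A, A + D, "Sen"),
        ppv=_ratio(A, A + B, "PPV"),
        acc=_ratio(A + C, counts.total, "Acc"),
    )
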