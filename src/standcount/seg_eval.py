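"""Pixel-level segmentation scoring against a reference mask.

The two masks are combined into a 4-valued overlay (reference coded 2,
prediction coded 1, cell-wise sum), from which the confusion counts and
precision / recall / F-measure / overall accuracy / Cohen's kappa follow.
Code 3 = both (TP), code 1 = predicted only (FP), code 2 = reference only
(FN), code 0 = neither (TN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .raster_io import BinaryMask

__all__ = ["OverlayLayer", "SegScores", "overlay", "scores",
           "scores_from_counts", "harmonic_fmeasure"]


@dataclass
class OverlayLayer:
    """Grid of codes {0: TN, 1: FP, 2: FN, 3: TP}."""

    data: np.ndarray

    def counts(self) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) pixel counts."""
        binc = np.bincount(self.data.ravel(), minlength=4)
        return int(binc[3]), int(binc[1]), int(binc[2]), int(binc[0])


@dataclass
class SegScores:
    TP: int
    FP: int
    FN: int
    TN: int
    precision: float | None   # percent
    recall: float | None      # percent
    fmeasure: float | None    # percent
    overall_accuracy: float   # percent
    kappa: float | None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN, "TN": self.TN,
            "precision": self.precision, "recall": self.recall,
            "fmeasure": self.fmeasure,
            "overall_accuracy": self.overall_accuracy, "kappa": self.kappa,
        }


def overlay(reference: BinaryMask, predicted: BinaryMask) -> OverlayLayer:
    """Cell-wise sum of (2 x reference) + prediction."""
    if reference.data.shape != predicted.data.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.data.shape} "
            f"vs predicted {predicted.data.shape}"
        )
    return OverlayLayer((2 * reference.data + predicted.data).astype(np.uint8))


def harmonic_fmeasure(precision: float, recall: float) -> float:
    """F-measure (harmonic mean) of precision and recall, same units in/out."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def scores_from_counts(TP: int, FP: int, FN: int, TN: int) -> SegScores:
    """Precision/recall/F (percent), overall accuracy and kappa from counts.

    Ratios with a zero denominator are reported as None (missing), not 0.
    """
    total = TP + FP + FN + TN
    if total == 0:
        raise ValueError("empty overlay")
    precision = 100.0 * TP / (TP + FP) if TP + FP else None
    recall = 100.0 * TP / (TP + FN) if TP + FN else None
    if precision is None or recall is None or precision + recall == 0:
        fm = None if (precision is None or recall is None) else 0.0
    else:
        fm = harmonic_fmeasure(precision, recall)
    oa = 100.0 * (TP + TN) / total
    # kappa: expected agreement from the marginals of the 2x2 matrix
    p_obs = (TP + TN) / total
    p_yes = ((TP + FP) / total) * ((TP + FN) / total)
    p_no = ((FN + TN) / total) * ((FP + TN) / total)
    p_exp = p_yes + p_no
    kappa = None if math.isclose(p_exp, 1.0) else (p_obs - p_exp) / (1.0 - p_exp)
    return SegScores(TP, FP, FN, TN, precision, recall, fm, oa, kappa)


def scores(layer: OverlayLayer) -> SegScores:
    """Score an overlay layer."""
    return scores_from_counts(*layer.counts())


def evaluate(reference: BinaryMask, predicted: BinaryMask) -> SegScores:
    """Convenience wrapper: overlay then score."""
    return scores(overlay(reference, predicted))
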