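"""Segmentation-agreement metrics.

The only metric used by the sensitivity framework is the Sørensen-Dice
similarity coefficient DSC(A, B) = 2|A∩B| / (|A| + |B|) between two binary
segmentations, 1 meaning complete overlap. When both masks are empty the
formula is 0/0; by convention the score is 1.0 (the two segmentations agree
that there is nothing) and the result carries a ``degenerate`` flag so that
downstream averaging can exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .volumes import DimensionError

__all__ = ["OverlapScore", "dice", "dice_per_label"]


@dataclass(frozen=True)
class OverlapScore:
    """Dice overlap between a reference and a predicted binary mask."""

    dsc: float
    n_ref: int
    n_pred: int
    n_intersect: int
    degenerate: bool = False


def dice(reference: np.ndarray, prediction: np.ndarray) -> OverlapScore:
    """Sørensen-Dice coefficient of two binary masks of equal shape.

    Non-boolean inputs are treated as foreground wherever non-zero.
    """
    reference = np.asarray(reference)
    prediction = np.asarray(prediction)
    if reference.shape != prediction.shape:
        raise DimensionError(
            f"mask shapes differ: {reference.shape} vs {prediction.shape}"
        )
    ref = reference.astype(bool)
    pred = prediction.astype(bool)
    n_ref = int(ref.sum())
    n_pred = int(pred.sum())
    n_int = int((ref & pred).sum())
    if n_ref + n_pred == 0:
        return OverlapScore(dsc=1.0, n_ref=0, n_pred=0, n_intersect=0, degenerate=True)
    return OverlapScore(
        dsc=2.0 * n_int / (n_ref + n_pred),
        n_ref=n_ref,
        n_pred=n_pred,
        n_intersect=n_int,
    )


def dice_per_label(
    reference: np.ndarray,
    prediction: np.ndarray,
    label_ids: Iterable[int],
) -> Mapping[int, OverlapScore]:
    """Dice per label ID, computed on per-ID binarizations of two label volumes."""
    label_ids = list(label_ids)
    if not label_ids:
        raise ValueError("label_ids must be non-empty")
    reference = np.asarray(reference)
    prediction = np.asarray(prediction)
    if reference.shape != prediction.shape:
        raise DimensionError(
            f"label volume shapes differ: {reference.shape} vs {prediction.shape}"
        )
    return {
        int(i): dice(reference == i, prediction == i) for i in label_ids
    }
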