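"""Counting evaluation metrics.

For N images with predicted counts C_pre and ground truth C_gt:

    MAE  = (1/N) * sum_i |C_pre_i - C_gt_i|
    RMSE = sqrt((1/N) * sum_i (C_pre_i - C_gt_i)^2)

and the relative counting accuracy, 100 * (1 - MAE / mean(C_gt)), expressed
as a percentage. The accuracy formula is the standard headline statistic for
field counting benchmarks; it requires a strictly positive mean true count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = ["CountEvaluation", "mae", "rmse", "relative_accuracy"]

Pairs = Sequence[Tuple[float, float]]  # (predicted, ground truth) per image


def _as_arrays(pairs: Pairs) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("metrics need at least one (predicted, true) pair")
    arr = arr.reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def mae(pairs: Pairs) -> float:
    pred, gt = _as_arrays(pairs)
    return float(np.mean(np.abs(pred - gt)))


def rmse(pairs: Pairs) -> float:
    pred, gt = _as_arrays(pairs)
    return float(np.sqrt(np.mean((pred - gt) ** 2)))


def relative_accuracy(pairs: Pairs) -> float:
    """100 * (1 - MAE / mean true count), in percent."""
    pred, gt = _as_arrays(pairs)
    mean_gt = float(np.mean(gt))
    if mean_gt <= 0:
        raise ValidationError(
            "relative accuracy is undefined for zero mean ground-truth count")
    return 100.0 * (1.0 - mae(pairs) / mean_gt)


@dataclass(frozen=True)
class CountEvaluation:
    """Paired per-image counts with the derived summary metrics."""

    pairs: Tuple[Tuple[float, float], ...]
    mae: float
    rmse: float
    relative_accuracy: float

    @classmethod
    def from_pairs(cls, pairs: Pairs) -> "CountEvaluation":
        return cls(
            pairs=tuple((float(p), float(g)) for p, g in pairs),
            mae=mae(pairs),
            rmse=rmse(pairs),
            relative_accuracy=relative_accuracy(pairs),
        )

    @property
    def n(self) -> int:
        return len(self.pairs)

    def to_dict(self) -> dict:
        return {
            "n_images": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "relative_accuracy": self.relative_accuracy,
        }
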