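"""Segmentation scoring against (consensus) expert ground truth.

Masks are compared pixelwise with mean squared error (on the 8-bit
{0, 255} coding, matching the magnitudes reported for fundus lesion
masks), Pearson correlation, the Sorensen-Dice overlap 2|X∩Y|/(|X|+|Y|),
and the confusion-matrix rates sensitivity, specificity and accuracy
(ground truth = positive class).  Batches report per-metric mean, sample
standard deviation, standard error and the normal-theory 95% confidence
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SegmentationScore",
    "consensus_ground_truth",
    "score_pair",
    "evaluate_batch",
]

_METRICS = ("mse", "corr", "dice", "sensitivity", "specificity", "accuracy")


@dataclass
class SegmentationScore:
    mse: float
    corr: float | None  # None when one mask is constant (undefined)
    corr_raw: float | None
    dice: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pixels: int


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    values = np.unique(arr)
    if not np.isin(values, (0, 1, 255)).all():
        raise ValueError(f"{name} is not a binary mask (values {values[:5]}...)")
    return arr > 0


def consensus_ground_truth(masks: list[np.ndarray]) -> np.ndarray:
    """Average expert masks into a consensus: pixelwise mean >= 0.5 -> 1.

    With two experts a disagreement averages to exactly 0.5 and the tie
    goes to the positive class.
    """
    if not masks:
        raise ValueError("need at least one mask")
    arrays = [_as_binary(m, f"mask {i}") for i, m in enumerate(masks)]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("expert masks have mismatched shapes")
    mean = np.mean([a.astype(float) for a in arrays], axis=0)
    return mean >= 0.5


def score_pair(
    pred: np.ndarray, truth: np.ndarray, mse_coding: int = 255
) -> SegmentationScore:
    """Score one predicted mask against ground truth.

    ``mse_coding`` chooses the intensity coding of the masks in the MSE
    (255 default, giving MSE = coding^2 * disagreement fraction; 1 gives
    the plain Hamming fraction).  Correlation is computed on the flattened
    {0,1} masks, reported clipped to [0, 1] with the raw value retained,
    and as missing (None) when either mask is constant.
    """
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    n = p.size
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))

    mse = float(mse_coding**2) * (fp + fn) / n
    dice = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / n

    if p.min() == p.max() or t.min() == t.max():
        corr_raw = corr = None
    else:
        corr_raw = float(np.corrcoef(p.ravel().astype(float), t.ravel().astype(float))[0, 1])
        corr = float(np.clip(corr_raw, 0.0, 1.0))
    return SegmentationScore(
        mse=mse,
        corr=corr,
        corr_raw=corr_raw,
        dice=dice,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n_pixels=n,
    )


def evaluate_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]], mse_coding: int = 255
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a batch of (pred, truth) pairs.

    Returns the per-pair score table and a per-metric summary with mean,
    sample std, standard error std/sqrt(n) and the normal-theory 95%
    confidence interval mean +/- 1.96 SE (point estimates only for n < 2).
    """
    if not pairs:
        raise ValueError("empty batch")
    rows = [asdict(score_pair(p, t, mse_coding)) for p, t in pairs]
    scores = pd.DataFrame(rows)

    summary_rows = []
    for metric in _METRICS:
        vals = scores[metric].dropna().astype(float)
        n = len(vals)
        row = {"metric": metric, "n": n, "mean": vals.mean() if n else math.nan}
        if n >= 2:
            std = float(vals.std(ddof=1))
            se = std / math.sqrt(n)
            row.update(
                std=std,
                se=se,
                ci_low=row["mean"] - 1.96 * se,
                ci_high=row["mean"] + 1.96 * se,
            )
        else:
            row.update(std=math.nan, se=math.nan, ci_low=math.nan, ci_high=math.nan)
        summary_rows.append(row)
    return scores, pd.DataFrame(summary_rows).set_index("metric")
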