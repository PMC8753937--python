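"""Evaluation protocol: pixel F1 and area under the precision-recall curve.

Soft maps are binarized at a threshold (default 0.5) for F1; the PR score
treats the soft values directly as pixel scores and uses the step-wise
average-precision rule (not trapezoids).  Sets of images are macro-averaged
(per-image metric, then mean) — flagged in output metadata since the
convention matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = ["EvalResult", "f1_score", "pr_auc", "evaluate_pair", "evaluate_set"]


@dataclass(frozen=True)
class EvalResult:
    f1: float
    pr_auc: float
    threshold: float
    n_pixels: int


def _check_pair(pred: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"pred shape {pred.shape} != gold shape {gold.shape}")
    if not np.all(np.isin(np.unique(gold), (0, 1))):
        raise ValueError("gold must be binary")
    return pred, gold.astype(bool)


def f1_score(pred: np.ndarray, gold: np.ndarray, threshold: float = 0.5) -> float:
    """Foreground F1 = 2TP / (2TP + FP + FN) after binarizing ``pred``.

    Both maps empty -> 1.0 (nothing to find, nothing claimed).
    """
    pred, gold = _check_pair(pred, gold)
    hard = pred >= threshold
    tp = np.count_nonzero(hard & gold)
    fp = np.count_nonzero(hard & ~gold)
    fn = np.count_nonzero(~hard & gold)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def pr_auc(pred: np.ndarray, gold: np.ndarray) -> float:
    """Average precision of the pixel scores against the binary gold mask.

    Requires at least one foreground and one background pixel; invariant
    under strictly monotone transforms of ``pred``.
    """
    pred, gold = _check_pair(pred, gold)
    if gold.all() or not gold.any():
        raise ValueError("gold must contain both foreground and background pixels")
    return float(average_precision_score(gold.ravel(), pred.ravel()))


def evaluate_pair(pred: np.ndarray, gold: np.ndarray, threshold: float = 0.5) -> EvalResult:
    return EvalResult(
        f1=f1_score(pred, gold, threshold),
        pr_auc=pr_auc(pred, gold),
        threshold=threshold,
        n_pixels=int(np.asarray(gold).size),
    )


def evaluate_set(
    preds: Sequence[np.ndarray],
    golds: Sequence[np.ndarray],
    threshold: float = 0.5,
) -> dict:
    """Per-image metrics plus macro averages."""
    if len(preds) != len(golds):
        raise ValueError("preds and golds differ in length")
    if not preds:
        raise ValueError("empty evaluation set")
    results = [evaluate_pair(p, g, threshold) for p, g in zip(preds, golds)]
    return {
        "per_image": results,
        "f1": float(np.mean([r.f1 for r in results])),
        "pr_auc": float(np.mean([r.pr_auc for r in results])),
        "threshold": threshold,
        "averaging": "macro",
    }
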