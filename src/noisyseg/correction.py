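"""Confidence-weighted label correction.

At the end of cycle j the per-pixel spread d = |best - worst| of the
cycle's historical predictions measures instability (large spread = low
confidence).  The compensation map blends the historical best with the
final prediction, Q = d * best + (1 - d) * final, and the labels move as a
running average anchored at the initial noisy mask:

    L[j+1] = 1/(j+1) * L0 + j/(j+1) * Q[j],   j = 1, 2, ...

so cycles 0 and 1 train on L0 itself and later cycles drift toward Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelState",
    "confidence_map",
    "compensation",
    "update_labels",
]


@dataclass(frozen=True)
class LabelState:
    """Initial noisy mask (frozen) and the current corrected soft mask."""

    initial: np.ndarray
    current: np.ndarray = None  # type: ignore[assignment]
    cycle_index: int = 0

    def __post_init__(self):
        initial = np.asarray(self.initial, dtype=np.float64).copy()
        if initial.ndim != 2:
            raise ValueError("initial must be a 2-D map")
        if initial.min() < 0 or initial.max() > 1:
            raise ValueError("initial must lie in [0, 1]")
        initial.flags.writeable = False
        object.__setattr__(self, "initial", initial)
        current = self.current
        if current is None:
            current = initial.copy()
        current = np.asarray(current, dtype=np.float64).copy()
        if current.shape != initial.shape:
            raise ValueError("current shape must match initial")
        if current.min() < -1e-12 or current.max() > 1 + 1e-12:
            raise ValueError("current must lie in [0, 1]")
        current.flags.writeable = False
        object.__setattr__(self, "current", current)
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be >= 0")
        if self.cycle_index <= 1 and not np.array_equal(current, initial):
            raise ValueError("labels may not differ from the initial mask before cycle 2")


def confidence_map(best: np.ndarray, worst: np.ndarray) -> np.ndarray:
    """Per-pixel rangeability d = |best - worst| in [0, 1].

    Large d means the prediction wandered during the cycle, i.e. LOW
    confidence in the final prediction at that pixel.
    """
    best = np.asarray(best, dtype=np.float64)
    worst = np.asarray(worst, dtype=np.float64)
    if best.shape != worst.shape:
        raise ValueError("best/worst shape mismatch")
    return np.abs(best - worst)


def compensation(D: np.ndarray, best: np.ndarray, final_pred: np.ndarray) -> np.ndarray:
    """Q = D * best + (1 - D) * final_pred, element-wise convex blend."""
    D = np.asarray(D, dtype=np.float64)
    best = np.asarray(best, dtype=np.float64)
    final_pred = np.asarray(final_pred, dtype=np.float64)
    if not (D.shape == best.shape == final_pred.shape):
        raise ValueError("shape mismatch among D, best, final_pred")
    if D.min() < 0 or D.max() > 1:
        raise ValueError("confidence map D must lie in [0, 1]")
    return D * best + (1.0 - D) * final_pred


def update_labels(state: LabelState, Q: np.ndarray, j: int) -> LabelState:
    """Running-average label move at the end of cycle ``j`` (j >= 1)."""
    if j < 1:
        raise ValueError("label correction starts after cycle 1 (j >= 1); "
                         "cycle 1 trains on the initial mask directly")
    Q = np.asarray(Q, dtype=np.float64)
    if Q.shape != state.initial.shape:
        raise ValueError("Q shape must match the label maps")
    if Q.min() < 0 or Q.max() > 1:
        raise ValueError("Q must lie in [0, 1]")
    new = (1.0 / (j + 1)) * state.initial + (j / (j + 1.0)) * Q
    new = np.clip(new, 0.0, 1.0)  # guards float error only
    return LabelState(initial=state.initial, current=new, cycle_index=j + 1)
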