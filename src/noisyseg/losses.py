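"""Training criteria: soft-target binary cross-entropy and the temporal
memory loss ``E(S, S_best) + lambda * E(S, L)``.

All functions take probability maps (post-sigmoid) and accept continuous
targets in [0, 1] — corrected labels and historical-best maps are soft.
The ``*_grad_logits`` helpers return the analytic gradient with respect to
pre-sigmoid logits, which is what the trainer backpropagates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "DEFAULT_CONFIG",
    "bce",
    "bce_grad",
    "warmup_loss",
    "temporal_memory_loss",
    "bce_grad_logits",
    "tml_grad_logits",
]


@dataclass(frozen=True)
class LossConfig:
    lambda_weight: float = 0.1
    clamp_eps: float = 1e-7

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if not (0 < self.clamp_eps < 0.5):
            raise ValueError("clamp_eps must lie in (0, 0.5)")


DEFAULT_CONFIG = LossConfig()


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def bce(pred: np.ndarray, target: np.ndarray, cfg: LossConfig = DEFAULT_CONFIG) -> float:
    """Mean binary cross-entropy with soft targets.

    ``-mean(t*log(s) + (1-t)*log(1-s))`` with ``s`` clamped to
    ``[clamp_eps, 1-clamp_eps]`` for log stability.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target)
    s = np.clip(pred, cfg.clamp_eps, 1.0 - cfg.clamp_eps)
    return float(-np.mean(target * np.log(s) + (1.0 - target) * np.log1p(-s)))


def bce_grad(pred: np.ndarray, target: np.ndarray, cfg: LossConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Gradient of :func:`bce` with respect to ``pred`` (the probabilities)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target)
    s = np.clip(pred, cfg.clamp_eps, 1.0 - cfg.clamp_eps)
    g = (-target / s + (1.0 - target) / (1.0 - s)) / pred.size
    # clamped region has zero gradient
    g[(pred < cfg.clamp_eps) | (pred > 1.0 - cfg.clamp_eps)] = 0.0
    return g


def warmup_loss(pred: np.ndarray, label: np.ndarray, cfg: LossConfig = DEFAULT_CONFIG) -> float:
    """Plain supervised criterion used while the bank accumulates: ``E(S, L)``."""
    return bce(pred, label, cfg)


def temporal_memory_loss(
    pred: np.ndarray,
    best: np.ndarray,
    label: np.ndarray,
    cfg: LossConfig = DEFAULT_CONFIG,
) -> float:
    """``E(S, S_best) + lambda * E(S, L)``.

    ``best`` is a constant target pulled from the memory bank — no gradient
    flows into it.  Callers without a populated bank must fall back to
    :func:`warmup_loss`; passing ``None`` here raises.
    """
    if best is None:
        raise ValueError("memory bank not populated; use warmup_loss instead")
    pred = np.asarray(pred, dtype=np.float64)
    best = np.asarray(best, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    _check_shapes(pred, best, label)
    return bce(pred, best, cfg) + cfg.lambda_weight * bce(pred, label, cfg)


def bce_grad_logits(probs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) for sigmoid outputs: ``(s - t) / N``."""
    return (probs - target) / probs.size


def tml_grad_logits(
    probs: np.ndarray,
    best: np.ndarray,
    label: np.ndarray,
    lambda_weight: float,
) -> np.ndarray:
    return ((probs - best) + lambda_weight * (probs - label)) / probs.size
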