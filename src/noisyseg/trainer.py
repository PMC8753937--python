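"""Training orchestration.

The schedule has an initialization block followed by M cycles of E epochs.
Each cycle starts with T warm-up epochs (plain supervised loss while the
memory bank accumulates) and continues with temporal-memory-loss epochs.
At the last epoch of every cycle the labels are corrected from the bank's
best/worst maps and the cycle-end prediction, and the bank is reset.

Learning rate: constant at ``base_lr`` until ``sgdr_start_epoch``, then
cosine annealing with warm restarts (period = epochs per cycle).  Weight
snapshots taken at the end of each annealing period are averaged (SWA);
by default the averaged model produces the cycle-end prediction.

Every image contributes four views per epoch (identity, horizontal flip,
vertical flip, both), treated as independent batch items; predictions are
flipped back to canonical orientation before entering the memory bank.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .bank import BankEmptyError, MemoryBank
from .correction import LabelState, compensation, confidence_map, update_labels
from .data import SampleRecord
from .losses import (
    LossConfig,
    bce,
    bce_grad_logits,
    temporal_memory_loss,
    tml_grad_logits,
    warmup_loss,
)
from .metrics import f1_score, pr_auc
from .model import Adam, UNet, get_weights, set_weights, sigmoid

__all__ = [
    "TrainConfig",
    "EpochPlan",
    "CorrectionReport",
    "RunResult",
    "ConfigError",
    "AUG_MODES",
    "VARIANTS",
    "augment",
    "invert_prediction",
    "sgdr_lr",
    "build_plan",
    "train_epoch",
    "run",
]

AUG_MODES = ("none", "hflip", "vflip", "hvflip")
VARIANTS = ("full", "no_tml", "q_is_s", "q_is_sbest")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    total_epochs: int = 100
    init_epochs: int = 50
    n_cycles: int = 5
    epochs_per_cycle: int = 10
    warmup_epochs: int = 3
    lambda_weight: float = 0.1
    base_lr: float = 7e-3
    sgdr_start_epoch: int | None = None  # default: init_epochs - epochs_per_cycle
    sgdr_period: int | None = None       # default: epochs_per_cycle
    swa_enabled: bool = True
    sj_from_swa: bool = True
    seed: int = 0
    model_width: int = 8
    model_depth: int = 4
    clamp_eps: float = 1e-7

    def resolved(self) -> "TrainConfig":
        out = self
        if out.sgdr_start_epoch is None:
            out = replace(out, sgdr_start_epoch=out.init_epochs - out.epochs_per_cycle)
        if out.sgdr_period is None:
            out = replace(out, sgdr_period=out.epochs_per_cycle)
        return out

    def validate(self) -> "TrainConfig":
        cfg = self.resolved()
        problems = []
        if cfg.init_epochs + cfg.n_cycles * cfg.epochs_per_cycle != cfg.total_epochs:
            problems.append(
                f"init_epochs + n_cycles*epochs_per_cycle must equal total_epochs "
                f"({cfg.init_epochs} + {cfg.n_cycles}*{cfg.epochs_per_cycle} != {cfg.total_epochs})"
            )
        if not (1 <= cfg.warmup_epochs < cfg.epochs_per_cycle):
            problems.append(
                f"warmup_epochs must satisfy 1 <= T < epochs_per_cycle "
                f"(T={cfg.warmup_epochs}, E={cfg.epochs_per_cycle})"
            )
        if cfg.sgdr_period != cfg.epochs_per_cycle:
            problems.append(
                f"sgdr_period must equal epochs_per_cycle "
                f"({cfg.sgdr_period} != {cfg.epochs_per_cycle})"
            )
        if cfg.sgdr_start_epoch < 0:
            problems.append("sgdr_start_epoch must be >= 0")
        if cfg.base_lr <= 0:
            problems.append("base_lr must be > 0")
        if cfg.lambda_weight < 0:
            problems.append("lambda_weight must be >= 0")
        if cfg.n_cycles < 0:
            problems.append("n_cycles must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))
        return cfg


@dataclass(frozen=True)
class EpochPlan:
    epoch: int
    phase: str  # init | warmup | tml
    cycle: int  # 0 during init, then 1..M
    lr: float
    correct_labels_at_end: bool


@dataclass
class CorrectionReport:
    """Per-epoch losses and per-cycle label quality (Fig-5-style curves)."""

    epochs: list = field(default_factory=list)   # dicts: epoch, phase, cycle, lr, train_loss, test_loss
    cycles: list = field(default_factory=list)   # dicts: cycle, label_f1, label_pr
    variant: str = "full"

    def to_dict(self) -> dict:
        return {"variant": self.variant, "epochs": self.epochs, "cycles": self.cycles}


@dataclass
class RunResult:
    model: UNet
    label_states: dict
    report: CorrectionReport
    config: TrainConfig


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def augment(arr: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return arr.copy()
    if mode == "hflip":
        return arr[:, ::-1].copy()
    if mode == "vflip":
        return arr[::-1, :].copy()
    if mode == "hvflip":
        return arr[::-1, ::-1].copy()
    raise ValueError(f"unknown augmentation mode {mode!r}")


def invert_prediction(pred: np.ndarray, mode: str) -> np.ndarray:
    # every flip is an involution, so reversal == application
    return augment(pred, mode)


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def sgdr_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing with warm restarts; flat at base_lr before start."""
    cfg = cfg.resolved()
    if epoch < cfg.sgdr_start_epoch:
        return cfg.base_lr
    phase = (epoch - cfg.sgdr_start_epoch) % cfg.sgdr_period
    return cfg.base_lr / 2.0 * (1.0 + np.cos(np.pi * phase / cfg.sgdr_period))


def build_plan(cfg: TrainConfig) -> list[EpochPlan]:
    cfg = cfg.validate()
    plan = []
    for epoch in range(cfg.total_epochs):
        if epoch < cfg.init_epochs:
            phase, cycle, correct = "init", 0, False
        else:
            k = epoch - cfg.init_epochs
            cycle = k // cfg.epochs_per_cycle + 1
            within = k % cfg.epochs_per_cycle
            phase = "warmup" if within < cfg.warmup_epochs else "tml"
            correct = within == cfg.epochs_per_cycle - 1
        plan.append(EpochPlan(epoch, phase, cycle, sgdr_lr(epoch, cfg), correct))
    return plan


# ---------------------------------------------------------------------------
# Epoch loop
# ---------------------------------------------------------------------------

def _clip_prob(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def standardize(image: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance normalization of network input."""
    image = np.asarray(image, dtype=np.float64)
    return (image - image.mean()) / max(image.std(), 1e-8)


def train_epoch(
    model: UNet,
    optimizer: Adam,
    records: list[SampleRecord],
    plan_rec: EpochPlan,
    bank: MemoryBank,
    states: dict[str, LabelState],
    cfg: TrainConfig,
    rng: np.random.Generator,
    use_tml: bool | None = None,
) -> float:
    """One pass over the dataset; returns the mean per-image loss.

    Each image forms a 4-view batch; one optimizer step per image.  In
    warm-up and TML phases the reversed view predictions are recorded into
    the memory bank (4 updates per image per epoch).
    """
    loss_cfg = LossConfig(lambda_weight=cfg.lambda_weight, clamp_eps=cfg.clamp_eps)
    if use_tml is None:
        use_tml = plan_rec.phase == "tml"
    order = rng.permutation(len(records))
    total = 0.0
    for idx in order:
        rec = records[idx]
        label = states[rec.image_id].current
        img = standardize(rec.image)
        x = np.stack([augment(img, m) for m in AUG_MODES])[:, None]
        lab_views = np.stack([augment(label, m) for m in AUG_MODES])

        best_views = None
        if use_tml:
            try:
                best = bank.get_best(rec.image_id)
            except BankEmptyError:
                best = None  # degenerate input: fall back to warm-up loss
            if best is not None:
                best_views = np.stack([augment(best, m) for m in AUG_MODES])

        logits = model.forward(x)
        probs = sigmoid(logits)
        p = probs[:, 0]
        if best_views is not None:
            loss = temporal_memory_loss(p, best_views, lab_views, loss_cfg)
            dlogits = tml_grad_logits(p, best_views, lab_views, cfg.lambda_weight)[:, None]
        else:
            loss = warmup_loss(p, lab_views, loss_cfg)
            dlogits = bce_grad_logits(p, lab_views)[:, None]
        optimizer.zero_grad()
        model.backward(dlogits)
        optimizer.lr = plan_rec.lr
        optimizer.step()

        if plan_rec.phase in ("warmup", "tml"):
            for v, mode in enumerate(AUG_MODES):
                canonical = invert_prediction(p[v], mode)
                bank.update(rec.image_id, _clip_prob(canonical, cfg.clamp_eps), label)
        total += loss
    return total / len(records)


def _eval_loss(model: UNet, records: list[SampleRecord], cfg: TrainConfig) -> float:
    loss_cfg = LossConfig(lambda_weight=cfg.lambda_weight, clamp_eps=cfg.clamp_eps)
    losses = []
    for rec in records:
        pred = model.predict(standardize(rec.image))
        target = rec.gold if rec.has_gold else rec.noisy
        losses.append(bce(pred, target, loss_cfg))
    return float(np.mean(losses))


class _SWA:
    def __init__(self):
        self.weights: list[np.ndarray] | None = None
        self.n = 0

    def update(self, model: UNet) -> None:
        ws = get_weights(model)
        if self.weights is None:
            self.weights = ws
        else:
            for avg, w in zip(self.weights, ws):
                avg += (w - avg) / (self.n + 1)
        self.n += 1

    def model(self, template: UNet) -> UNet:
        clone = copy.deepcopy(template)
        set_weights(clone, self.weights)
        return clone


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run(
    cfg: TrainConfig,
    train_records: list[SampleRecord],
    test_records: list[SampleRecord] | None = None,
    variant: str = "full",
) -> RunResult:
    """Execute the whole schedule and return model, labels and report."""
    cfg = cfg.validate()
    if not train_records:
        raise ValueError("empty training dataset")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")

    rng = np.random.default_rng(cfg.seed)
    model = UNet(1, width=cfg.model_width, depth=cfg.model_depth, seed=cfg.seed)
    optimizer = Adam(model.parameters(), cfg.base_lr)
    bank = MemoryBank()
    states = {r.image_id: LabelState(initial=r.noisy) for r in train_records}
    swa = _SWA() if cfg.swa_enabled else None
    report = CorrectionReport(variant=variant)

    for rec in train_records:
        rec.lock_gold()
    try:
        _log_cycle(report, 0, states, train_records)
        plan = build_plan(cfg)
        for p in plan:
            if p.phase != "init" and (p.epoch - cfg.init_epochs) % cfg.epochs_per_cycle == 0:
                bank.reset()  # new cycle: argmin/argmax restart against fresh L^j
            use_tml = p.phase == "tml" and variant != "no_tml"
            train_loss = train_epoch(
                model, optimizer, train_records, p, bank, states, cfg, rng, use_tml=use_tml
            )
            test_loss = _eval_loss(model, test_records, cfg) if test_records else None
            if swa is not None and p.epoch >= cfg.sgdr_start_epoch and \
                    (p.epoch - cfg.sgdr_start_epoch) % cfg.sgdr_period == cfg.sgdr_period - 1:
                swa.update(model)
            report.epochs.append({
                "epoch": p.epoch, "phase": p.phase, "cycle": p.cycle, "lr": p.lr,
                "train_loss": float(train_loss),
                "test_loss": None if test_loss is None else float(test_loss),
            })
            if p.correct_labels_at_end:
                pred_model = model
                if swa is not None and cfg.sj_from_swa and swa.n > 0:
                    pred_model = swa.model(model)
                for rec_i in train_records:
                    final_pred = _clip_prob(pred_model.predict(standardize(rec_i.image)), cfg.clamp_eps)
                    best = bank.get_best(rec_i.image_id)
                    worst = bank.get_worst(rec_i.image_id)
                    if variant == "q_is_s":
                        q = final_pred
                    elif variant == "q_is_sbest":
                        q = best
                    else:
                        q = compensation(confidence_map(best, worst), best, final_pred)
                    states[rec_i.image_id] = update_labels(states[rec_i.image_id], q, p.cycle)
                bank.reset()
                _log_cycle(report, p.cycle, states, train_records)
    finally:
        for rec in train_records:
            rec.unlock_gold()
    return RunResult(model=model, label_states=states, report=report, config=cfg)


def _log_cycle(report, cycle, states, records):
    """Evaluation-only logging of corrected-label quality vs gold."""
    f1s, prs = [], []
    for rec in records:
        if not rec.has_gold:
            continue
        locked = rec._gold_locked
        rec.unlock_gold()
        gold = rec.gold
        if locked:
            rec.lock_gold()
        cur = states[rec.image_id].current
        f1s.append(f1_score(cur, gold))
        if gold.any() and not gold.all():
            prs.append(pr_auc(cur, gold))
    if f1s:
        report.cycles.append({
            "cycle": cycle,
            "label_f1": float(np.mean(f1s)),
            "label_pr": float(np.mean(prs)) if prs else None,
        })
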