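"""Per-image, per-pixel memory bank of historical best/worst predictions.

Within one training cycle the supervision map L is fixed, so keeping the
prediction with the smallest (largest) absolute deviation from L at each
pixel — updated incrementally with strict-inequality replacement — equals
the argmin (argmax) over every prediction recorded that cycle, while
storing only two maps and their deviations per image.  Ties keep the
earliest epoch's value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BankEmptyError", "BankEntry", "MemoryBank"]


class BankEmptyError(RuntimeError):
    """Raised when best/worst maps are requested before any update."""


@dataclass
class BankEntry:
    best: np.ndarray
    worst: np.ndarray
    best_dev: np.ndarray
    worst_dev: np.ndarray
    n_updates: int
    label_digest: str = ""


def _digest(label: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(label, dtype=np.float64).tobytes()).hexdigest()


class MemoryBank:
    """Dict-like store keyed by image id."""

    def __init__(self):
        self._entries: dict[str, BankEntry] = {}

    def image_ids(self) -> list[str]:
        return list(self._entries)

    def reset(self, image_ids=None) -> None:
        """Clear entries (all, or the listed ids) for a new cycle. Idempotent."""
        if image_ids is None:
            self._entries.clear()
        else:
            for iid in image_ids:
                self._entries.pop(iid, None)

    def n_updates(self, image_id: str) -> int:
        entry = self._entries.get(image_id)
        return 0 if entry is None else entry.n_updates

    def update(self, image_id: str, prediction: np.ndarray, label: np.ndarray) -> None:
        """Record one epoch's prediction (canonical orientation) against the
        cycle's fixed supervision map."""
        pred = np.asarray(prediction, dtype=np.float64)
        lab = np.asarray(label, dtype=np.float64)
        if pred.shape != lab.shape:
            raise ValueError(f"prediction shape {pred.shape} != label shape {lab.shape}")
        dev = np.abs(pred - lab)
        entry = self._entries.get(image_id)
        if entry is None:
            self._entries[image_id] = BankEntry(
                best=pred.copy(), worst=pred.copy(),
                best_dev=dev.copy(), worst_dev=dev.copy(),
                n_updates=1, label_digest=_digest(lab),
            )
            return
        if entry.label_digest != _digest(lab):
            raise ValueError(
                f"supervision map for {image_id!r} changed mid-cycle; "
                "reset the bank at cycle boundaries"
            )
        better = dev < entry.best_dev
        entry.best[better] = pred[better]
        entry.best_dev[better] = dev[better]
        worse = dev > entry.worst_dev
        entry.worst[worse] = pred[worse]
        entry.worst_dev[worse] = dev[worse]
        entry.n_updates += 1

    def _get(self, image_id: str) -> BankEntry:
        entry = self._entries.get(image_id)
        if entry is None or entry.n_updates < 1:
            raise BankEmptyError(
                f"no predictions recorded for {image_id!r} this cycle"
            )
        return entry

    def get_best(self, image_id: str) -> np.ndarray:
        return self._get(image_id).best.copy()

    def get_worst(self, image_id: str) -> np.ndarray:
        return self._get(image_id).worst.copy()

    # -- optional persistence (resume interrupted runs) ---------------------

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        meta: dict[str, np.ndarray] = {}
        for iid, e in self._entries.items():
            arrays[f"{iid}/best"] = e.best
            arrays[f"{iid}/worst"] = e.worst
            arrays[f"{iid}/best_dev"] = e.best_dev
            arrays[f"{iid}/worst_dev"] = e.worst_dev
            meta[f"{iid}/n"] = np.array([e.n_updates])
            meta[f"{iid}/digest"] = np.frombuffer(bytes.fromhex(e.label_digest), dtype=np.uint8)
        np.savez_compressed(path, **arrays, **meta)

    @classmethod
    def load(cls, path: str | Path) -> "MemoryBank":
        bank = cls()
        with np.load(path) as npz:
            ids = {k.rsplit("/", 1)[0] for k in npz.files}
            for iid in ids:
                bank._entries[iid] = BankEntry(
                    best=npz[f"{iid}/best"],
                    worst=npz[f"{iid}/worst"],
                    best_dev=npz[f"{iid}/best_dev"],
                    worst_dev=npz[f"{iid}/worst_dev"],
                    n_updates=int(npz[f"{iid}/n"][0]),
                    label_digest=npz[f"{iid}/digest"].tobytes().hex(),
                )
        return bank
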