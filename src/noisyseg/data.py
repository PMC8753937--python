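"""Sample records and on-disk dataset layout.

A dataset is a directory with ``images/``, ``noisy/`` and (optionally)
``gold/`` sub-directories of 8-bit PNGs plus a ``manifest.json`` recording
generator seeds and noise parameters.  Masks are stored with foreground=255.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio

__all__ = [
    "GoldAccessError",
    "SampleRecord",
    "save_dataset",
    "load_dataset",
]


class GoldAccessError(RuntimeError):
    """Raised when training-path code touches a gold mask."""


class SampleRecord:
    """One training image with its noisy mask and (hidden) gold mask.

    The gold mask exists for evaluation only.  While a trainer holds the
    record it calls :meth:`lock_gold`; any read of :attr:`gold` then raises
    :class:`GoldAccessError`.  Evaluation code unlocks explicitly.
    """

    def __init__(
        self,
        image: np.ndarray,
        noisy: np.ndarray,
        gold: np.ndarray | None = None,
        image_id: str = "",
        meta: dict | None = None,
    ):
        image = np.asarray(image, dtype=np.float64)
        noisy = np.asarray(noisy, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("image must be a 2-D array")
        if noisy.shape != image.shape:
            raise ValueError("noisy mask shape must match image shape")
        if gold is not None:
            gold = np.asarray(gold, dtype=np.float64)
            if gold.shape != image.shape:
                raise ValueError("gold mask shape must match image shape")
            gold = gold.copy()
            gold.flags.writeable = False
        self._image = image.copy()
        self._image.flags.writeable = False
        self._noisy = noisy.copy()
        self._noisy.flags.writeable = False
        self._gold = gold
        self._gold_locked = False
        self.image_id = image_id
        self.meta = dict(meta or {})

    @property
    def image(self) -> np.ndarray:
        return self._image

    @property
    def noisy(self) -> np.ndarray:
        """The initial noisy label map L0 (frozen)."""
        return self._noisy

    @property
    def has_gold(self) -> bool:
        return self._gold is not None

    @property
    def gold(self) -> np.ndarray:
        if self._gold_locked:
            raise GoldAccessError(
                f"gold mask of {self.image_id!r} is locked during training"
            )
        if self._gold is None:
            raise KeyError(f"record {self.image_id!r} carries no gold mask")
        return self._gold

    def lock_gold(self) -> None:
        self._gold_locked = True

    def unlock_gold(self) -> None:
        self._gold_locked = False


def _to_u8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(arr, dtype=float) * 255.0), 0, 255).astype(np.uint8)


def save_dataset(records: Sequence[SampleRecord], out_dir: str | Path, manifest: dict | None = None) -> Path:
    """Write records as PNG trees + manifest.json; returns the directory."""
    out = Path(out_dir)
    for sub in ("images", "noisy", "gold"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        name = f"{rec.image_id or len(entries):>04}.png" if not rec.image_id else f"{rec.image_id}.png"
        iio.imwrite(out / "images" / name, _to_u8(rec.image))
        iio.imwrite(out / "noisy" / name, _to_u8(rec.noisy))
        if rec.has_gold:
            locked = rec._gold_locked
            rec.unlock_gold()
            iio.imwrite(out / "gold" / name, _to_u8(rec.gold))
            if locked:
                rec.lock_gold()
        entries.append({"id": rec.image_id, "file": name, "meta": rec.meta})
    payload = {"records": entries}
    if manifest:
        payload.update(manifest)
    (out / "manifest.json").write_text(json.dumps(payload, indent=2))
    return out


def load_dataset(in_dir: str | Path) -> list[SampleRecord]:
    """Load a dataset directory written by :func:`save_dataset`.

    Also accepts the public DRIVE/STARE/CHASE-style layout: any directory
    holding ``images/`` and ``noisy/`` PNGs with matching filenames, plus an
    optional ``gold/``.
    """
    root = Path(in_dir)
    img_dir = root / "images"
    noisy_dir = root / "noisy"
    gold_dir = root / "gold"
    if not img_dir.is_dir() or not noisy_dir.is_dir():
        raise FileNotFoundError(f"{root} lacks images/ and noisy/ sub-directories")
    manifest = {}
    mpath = root / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    meta_by_file = {e["file"]: e.get("meta", {}) for e in manifest.get("records", [])}
    records = []
    for path in sorted(img_dir.glob("*.png")):
        img = np.asarray(iio.imread(path), dtype=np.float64)
        if img.ndim == 3:  # RGB -> luminance
            img = img.mean(axis=2)
        img /= 255.0
        noisy = _read_mask(noisy_dir / path.name)
        gold = _read_mask(gold_dir / path.name) if (gold_dir / path.name).exists() else None
        records.append(
            SampleRecord(
                img, noisy, gold,
                image_id=path.stem,
                meta=meta_by_file.get(path.name, {}),
            )
        )
    if not records:
        raise FileNotFoundError(f"no PNG images found under {img_dir}")
    return records


def _read_mask(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr >= 128).astype(np.float64)
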