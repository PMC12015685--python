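"""Image-chip data model, PNG round-tripping, splits and annotation budgets.

The unit of analysis is a single-plant RGB image chip.  Chips carry an
explicit declared value range so the [0, 1] storage convention and the
[-1, 1] GAN convention can never be silently mixed.  Splitting follows the
80:20 train/test, then 80:20 train/validation protocol, with the test set
held fixed while the annotation budget (fraction of revealed training
labels) varies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Sentinel label for chips whose annotation is hidden from the learner.
UNLABELED = -1

_ALLOWED_RANGES = ((0.0, 1.0), (-1.0, 1.0))


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf (so 0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass
class ImageChip:
    """A square H x W x 3 real-valued image with a declared value range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"chip must be H x W x 3, got shape {px.shape}")
        if px.shape[0] != px.shape[1]:
            raise ValueError("chip must be square")
        vr = (float(self.value_range[0]), float(self.value_range[1]))
        if vr not in _ALLOWED_RANGES:
            raise ValueError(f"value_range must be one of {_ALLOWED_RANGES}")
        lo, hi = vr
        if px.min() < lo - 1e-6 or px.max() > hi + 1e-6:
            raise ValueError("pixel values fall outside the declared range")
        self.pixels = px
        self.value_range = vr

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ChipDataset:
    """Chips with per-chip labels in {0, 1, UNLABELED} and unique string ids.

    ``provenance`` is generator-side ground truth (speckle masks, canopy
    geometry) kept only for evaluation; classifiers never read it.
    """

    chips: list[ImageChip]
    labels: np.ndarray
    ids: list[str]
    provenance: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.chips) == len(self.labels) == len(self.ids)):
            raise ValueError("chips, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("chip ids must be unique")
        bad = set(np.unique(self.labels)) - {0, 1, UNLABELED}
        if bad:
            raise ValueError(f"labels must be 0, 1 or UNLABELED; got {sorted(bad)}")
        if self.provenance is not None and len(self.provenance) != len(self.chips):
            raise ValueError("provenance must align with chips")

    def __len__(self) -> int:
        return len(self.chips)

    @property
    def all_labeled(self) -> bool:
        return bool(np.all(self.labels != UNLABELED))

    def pixel_array(self) -> np.ndarray:
        """Stack chips into (N, H, W, 3) float32; requires a common size."""
        return np.stack([c.pixels for c in self.chips]).astype(np.float32)

    def subset(self, indices) -> "ChipDataset":
        indices = list(indices)
        prov = [self.provenance[i] for i in indices] if self.provenance else None
        return ChipDataset(chips=[self.chips[i] for i in indices],
                           labels=self.labels[indices],
                           ids=[self.ids[i] for i in indices],
                           provenance=prov)

    def with_labels_masked(self) -> "ChipDataset":
        return ChipDataset(chips=self.chips,
                           labels=np.full(len(self), UNLABELED, dtype=np.int64),
                           ids=list(self.ids), provenance=self.provenance)


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    val_fraction_of_train: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_fraction, self.val_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


# ---------------------------------------------------------------------------
# IO


def save_dataset(ds: ChipDataset, out_dir: str | Path) -> None:
    """Write chips as 8-bit PNGs ``chip_<index>.png`` plus ``labels.csv``.

    Chips must be in [0, 1]; unlabeled chips are omitted from labels.csv
    (that is what marks them unlabeled on reload).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for chip, label, cid in zip(ds.chips, ds.labels, ds.ids):
        if chip.value_range != (0.0, 1.0):
            raise ValueError("save_dataset expects chips in [0, 1]")
        iio.imwrite(out / f"{cid}.png",
                    np.round(chip.pixels * 255.0).astype(np.uint8))
        if label != UNLABELED:
            rows.append({"chip_id": cid, "label": int(label)})
    pd.DataFrame(rows, columns=["chip_id", "label"]).to_csv(
        out / "labels.csv", index=False)


def load_dataset(chip_dir: str | Path, labels_file: str | Path | None = None) -> ChipDataset:
    """Load every ``*.png``/``*.tif`` chip in a directory; ids are file stems.

    Chips listed in ``labels_file`` get their label; the rest are UNLABELED.
    Non-3-channel images, duplicate ids in the labels table, and label ids
    without an image file are each rejected with a distinct message.
    """
    chip_dir = Path(chip_dir)
    files = sorted(list(chip_dir.glob("*.png")) + list(chip_dir.glob("*.tif"))
                   + list(chip_dir.glob("*.tiff")))
    if not files:
        raise FileNotFoundError(f"no chip images found in {chip_dir}")
    if labels_file is None and (chip_dir / "labels.csv").exists():
        labels_file = chip_dir / "labels.csv"
    label_map: dict[str, int] = {}
    if labels_file is not None:
        table = pd.read_csv(labels_file)
        if table["chip_id"].duplicated().any():
            dupes = table.loc[table["chip_id"].duplicated(), "chip_id"].tolist()
            raise ValueError(f"duplicate chip ids in labels table: {dupes[:5]}")
        label_map = dict(zip(table["chip_id"].astype(str), table["label"].astype(int)))
    stems = {f.stem for f in files}
    missing = sorted(set(label_map) - stems)
    if missing:
        raise FileNotFoundError(f"labelled ids without an image file: {missing[:5]}")
    chips, labels, ids = [], [], []
    for f in files:
        raw = iio.imread(f)
        if raw.ndim != 3 or raw.shape[2] != 3:
            raise ValueError(
                f"{f.name}: expected a 3-channel RGB image, got shape {raw.shape}")
        px = raw.astype(np.float32) / 255.0
        chips.append(ImageChip(px, (0.0, 1.0)))
        ids.append(f.stem)
        labels.append(label_map.get(f.stem, UNLABELED))
    return ChipDataset(chips=chips, labels=np.array(labels), ids=ids)


# ---------------------------------------------------------------------------
# Geometry / range transforms


def resize_chip(chip: ImageChip, size: int) -> ImageChip:
    """Bilinear resize (half-pixel-centre convention) to ``size`` x ``size``."""
    if size < 8:
        raise ValueError("target size must be >= 8")
    if size == chip.size:
        return ImageChip(chip.pixels.copy(), chip.value_range)
    out = bilinear_resize(chip.pixels, size, size)
    lo, hi = chip.value_range
    return ImageChip(np.clip(out, lo, hi), chip.value_range)


def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Vectorised bilinear interpolation; source pixels sit at half-integer
    centres (the convention shared by most imaging libraries)."""
    h, w = img.shape[:2]
    ys = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    y0 = np.clip(np.floor(ys), 0, h - 1).astype(int)
    x0 = np.clip(np.floor(xs), 0, w - 1).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0).astype(np.float32)
    wx = np.clip(xs - x0, 0.0, 1.0).astype(np.float32)
    ia = img[np.ix_(y0, x0)]
    ib = img[np.ix_(y0, x1)]
    ic = img[np.ix_(y1, x0)]
    idd = img[np.ix_(y1, x1)]
    wy = wy[:, None, None] if img.ndim == 3 else wy[:, None]
    wx = wx[None, :, None] if img.ndim == 3 else wx[None, :]
    top = ia * (1 - wx) + ib * wx
    bot = ic * (1 - wx) + idd * wx
    return (top * (1 - wy) + bot * wy).astype(np.float32)


def normalize_for_gan(chip: ImageChip) -> ImageChip:
    """Map [0, 1] -> [-1, 1] (x -> 2x - 1) to match the generator's Tanh range."""
    if chip.value_range != (0.0, 1.0):
        raise ValueError("chip is not in [0, 1]; refusing to normalise twice")
    return ImageChip(2.0 * chip.pixels - 1.0, (-1.0, 1.0))


def denormalize_from_gan(chip: ImageChip) -> ImageChip:
    if chip.value_range != (-1.0, 1.0):
        raise ValueError("chip is not in [-1, 1]")
    return ImageChip((chip.pixels + 1.0) / 2.0, (0.0, 1.0))


# ---------------------------------------------------------------------------
# Splitting and annotation budgets


def split_dataset(ds: ChipDataset, spec: SplitSpec | None = None
                  ) -> tuple[ChipDataset, ChipDataset, ChipDataset]:
    """Deterministic (train, val, test) partition.

    Test size is the round-half-up complement of the training pool and stays
    fixed across annotation budgets; the training pool is further split into
    train and validation.  All chips must be labeled (budgets are applied
    after splitting).
    """
    spec = spec or SplitSpec()
    if not ds.all_labeled:
        raise ValueError("split_dataset requires fully labeled data; "
                         "apply annotation budgets after splitting")
    n = len(ds)
    n_pool = round_half_up(spec.train_fraction * n)
    n_val = round_half_up(spec.val_fraction_of_train * n_pool)
    order = np.random.default_rng(spec.seed).permutation(n)
    pool_idx, test_idx = order[:n_pool], order[n_pool:]
    val_idx, train_idx = pool_idx[:n_val], pool_idx[n_val:]
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)


def subsample_budget(train: ChipDataset, fraction: float, seed: int
                     ) -> tuple[ChipDataset, ChipDataset]:
    """Reveal labels for ceil(fraction * n) chips, stratified by class; the
    remainder is returned with labels masked to UNLABELED."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("budget fraction must lie in (0, 1]")
    if not train.all_labeled:
        raise ValueError("training pool must be fully labeled before budgeting")
    n = len(train)
    k = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    if k >= n:
        return train, train.subset([])
    # largest-remainder apportionment over the classes present, >=1 per class
    classes = [c for c in (0, 1) if np.any(train.labels == c)]
    counts = {c: int(np.sum(train.labels == c)) for c in classes}
    quota = {c: k * counts[c] / n for c in classes}
    alloc = {c: int(math.floor(quota[c])) for c in classes}
    if len(classes) > 1 and k >= len(classes):
        for c in classes:
            alloc[c] = max(alloc[c], 1)
    rema = sorted(classes, key=lambda c: quota[c] - math.floor(quota[c]), reverse=True)
    i = 0
    while sum(alloc.values()) < k:
        c = rema[i % len(rema)]
        if alloc[c] < counts[c]:
            alloc[c] += 1
        i += 1
    while sum(alloc.values()) > k:
        c = max(classes, key=lambda c: alloc[c])
        alloc[c] -= 1
    chosen: list[int] = []
    for c in classes:
        idx = np.flatnonzero(train.labels == c)
        chosen.extend(rng.choice(idx, size=alloc[c], replace=False).tolist())
    chosen_set = set(chosen)
    rest = [i for i in range(n) if i not in chosen_set]
    return train.subset(sorted(chosen)), train.subset(rest).with_labels_masked()


def save_split_manifest(path: str | Path, splits: dict[str, ChipDataset],
                        spec: SplitSpec) -> None:
    payload = {"seed": spec.seed,
               "train_fraction": spec.train_fraction,
               "val_fraction_of_train": spec.val_fraction_of_train,
               "partitions": {name: list(ds.ids) for name, ds in splits.items()}}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_split_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
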