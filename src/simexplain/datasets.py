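"""Labeled image datasets, stratified splits and verification-pair construction.

The pair protocol follows the classic Siamese verification setup: for every
anchor image one same-class mate (label 0, "similar") and one different-class
mate (label 1, "dissimilar") are drawn at random, giving a balanced pair set
of size ``2 * len(dataset)``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class LabeledImage:
    """A single image with its class label.

    pixels are H x W x C uint8 (C = 1 or 3); image_id is unique within a
    dataset (the source path for folder-loaded data, generated otherwise).
    """

    pixels: np.ndarray
    class_label: str
    image_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"pixels must be HxWx1 or HxWx3, got {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape}")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabeledDataset:
    """An ordered collection of labeled images with an ordered label set."""

    images: list[LabeledImage]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted({im.class_label for im in self.images})
        unknown = {im.class_label for im in self.images} - set(self.classes)
        if unknown:
            raise ValueError(f"images carry labels outside the class set: {unknown}")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.images)

    def by_class(self) -> dict[str, list[LabeledImage]]:
        out: dict[str, list[LabeledImage]] = {c: [] for c in self.classes}
        for im in self.images:
            out[im.class_label].append(im)
        return out

    def image_ids(self) -> list[str]:
        return [im.image_id for im in self.images]


@dataclass
class DatasetSplit:
    train: LabeledDataset
    val: LabeledDataset
    test: LabeledDataset


@dataclass(frozen=True)
class ImagePair:
    """Two images with a binary label: 0 = same class, 1 = different class."""

    a: LabeledImage
    b: LabeledImage
    label: int

    def __post_init__(self) -> None:
        same = self.a.class_label == self.b.class_label
        if self.label not in (0, 1) or (self.label == 0) != same:
            raise ValueError(
                f"pair label {self.label} inconsistent with classes "
                f"({self.a.class_label!r}, {self.b.class_label!r})"
            )


def load_image_folder(root: str | Path) -> LabeledDataset:
    """Load a directory-per-class image tree into a :class:`LabeledDataset`.

    Every subdirectory of ``root`` is a class; every decodable PNG/JPEG file
    inside becomes one image labeled by the directory name. Ordering is
    lexicographic by path so repeated loads are identical. Undecodable files
    are skipped with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(
            f"dataset root {root} must contain at least 2 class directories, "
            f"found {len(class_dirs)}"
        )
    images: list[LabeledImage] = []
    for cdir in class_dirs:
        for fp in sorted(cdir.iterdir()):
            if fp.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(fp) as img:
                    arr = np.asarray(img.convert("RGB"))
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping undecodable image %s: %s", fp, exc)
                continue
            images.append(
                LabeledImage(pixels=arr, class_label=cdir.name, image_id=str(fp))
            )
    return LabeledDataset(images=images, classes=[d.name for d in class_dirs])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    ds: LabeledDataset, test_frac: float, val_frac: float, seed: int
) -> DatasetSplit:
    """Split a dataset into train/val/test preserving per-class proportions.

    Per class, the test count is ``round_half_up(n * test_frac)`` with a floor
    of one image when the class has at least two. Validation images are then
    drawn from the remaining train pool: the total validation count is
    ``round_half_up(pool * val_frac)`` apportioned across classes by largest
    remainder, so the overall validation fraction is exact even when per-class
    rounding would overshoot. Classes with a single image go entirely to train
    with a warning. Fully reproducible under ``seed``.
    """
    if not (0 < test_frac < 1):
        raise ValueError(f"test_frac must be in (0,1), got {test_frac}")
    if not (0 <= val_frac < 1):
        raise ValueError(f"val_frac must be in [0,1), got {val_frac}")
    rng = np.random.default_rng(seed)
    train: list[LabeledImage] = []
    val: list[LabeledImage] = []
    test: list[LabeledImage] = []
    pools: list[tuple[str, list[LabeledImage]]] = []  # per-class train pools
    for cls, members in ds.by_class().items():
        if len(members) < 2:
            logger.warning("class %r has a single image; assigned to train", cls)
            train.extend(members)
            continue
        order = rng.permutation(len(members))
        n_test = max(1, _round_half_up(len(members) * test_frac))
        n_test = min(n_test, len(members) - 1)  # keep at least one train image
        shuffled = [members[i] for i in order]
        test.extend(shuffled[:n_test])
        pools.append((cls, shuffled[n_test:]))

    pool_total = sum(len(p) for _, p in pools)
    n_val_total = _round_half_up(pool_total * val_frac)
    # largest-remainder apportionment of the exact validation total
    quotas = [len(p) * val_frac for _, p in pools]
    base = [min(int(math.floor(q)), len(p) - 1) for q, (_, p) in zip(quotas, pools)]
    leftover = n_val_total - sum(base)
    remainders = sorted(
        range(len(pools)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    counts = list(base)
    for i in remainders:
        if leftover <= 0:
            break
        if counts[i] < len(pools[i][1]) - 1:
            counts[i] += 1
            leftover -= 1
    for (cls, pool), n_val in zip(pools, counts):
        val.extend(pool[:n_val])
        train.extend(pool[n_val:])

    classes = ds.classes
    return DatasetSplit(
        train=LabeledDataset(train, classes=classes),
        val=LabeledDataset(val, classes=classes),
        test=LabeledDataset(test, classes=classes),
    )


def build_pairs(ds: LabeledDataset, seed: int) -> list[ImagePair]:
    """Build verification pairs: per anchor one same-class and one
    different-class mate, uniformly sampled (never the anchor itself).

    Returns ``2 * len(ds)`` pairs when all classes have at least two images;
    anchors in singleton classes skip their label-0 pair with a warning.
    """
    if len(ds.classes) < 2:
        raise ValueError("pair construction requires at least 2 classes")
    rng = np.random.default_rng(seed)
    by_class = ds.by_class()
    pairs: list[ImagePair] = []
    for anchor in ds.images:
        same = [im for im in by_class[anchor.class_label] if im.image_id != anchor.image_id]
        if same:
            mate = same[rng.integers(len(same))]
            pairs.append(ImagePair(a=anchor, b=mate, label=0))
        else:
            logger.warning(
                "class %r has a single image; skipping the same-class pair for %s",
                anchor.class_label,
                anchor.image_id,
            )
        other = [
            im for cls, members in by_class.items() if cls != anchor.class_label
            for im in members
        ]
        mate = other[rng.integers(len(other))]
        pairs.append(ImagePair(a=anchor, b=mate, label=1))
    return pairs


def write_pair_manifest(pairs: Sequence[ImagePair], path: str | Path) -> None:
    """Write pairs as CSV with header ``id_a,id_b,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "label"])
        for p in pairs:
            writer.writerow([p.a.image_id, p.b.image_id, p.label])


def read_pair_manifest(path: str | Path, ds: LabeledDataset) -> list[ImagePair]:
    """Resolve a CSV pair manifest against a dataset's image ids."""
    index = {im.image_id: im for im in ds.images}
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append(
                ImagePair(a=index[row["id_a"]], b=index[row["id_b"]], label=int(row["label"]))
            )
    return pairs


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Write a CSV of ``image_id,split`` rows for a dataset split."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "split"])
        for name in ("train", "val", "test"):
            for im in getattr(split, name).images:
                writer.writerow([im.image_id, name])
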