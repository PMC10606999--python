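"""Heatmap-driven crop refinement of a training set.

For each anchor image, a random same-class mate is drawn; if the model rates
the pair confidently similar (similarity strictly above the gate, 80% by
default), the anchor's factual Grad-CAM heatmap is binarized at a fraction of
its maximum, the largest 8-connected hot component is boxed, and the anchor
is replaced by that crop. Anchors without a confident mate are kept
unchanged, so the refined dataset has the same cardinality, labels and ids —
only pixel content changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .datasets import ImagePair, LabeledDataset, LabeledImage
from .gradcam import explain_pair
from .model import SiameseNetwork, similarity_score

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)
_MIN_SIDE = 8  # crops are expanded to this minimum side so they stay valid images


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel rectangle [x_min, x_max) x [y_min, y_max), origin
    top-left, x = column, y = row."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    fallback: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def area(self) -> int:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y_min:self.y_max, self.x_min:self.x_max]


@dataclass
class RefinementConfig:
    similarity_gate: float = 0.80
    binarize_frac: float = 0.5
    max_mate_retries: int = 5
    min_box_frac: float = 0.01

    def __post_init__(self) -> None:
        for name in ("similarity_gate", "binarize_frac", "min_box_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.max_mate_retries < 1:
            raise ValueError("max_mate_retries must be >= 1")


def select_confident_mate(model, ds: LabeledDataset, anchor: LabeledImage,
                          cfg: RefinementConfig, seed: int) -> Optional[LabeledImage]:
    """Draw random distinct same-class mates until one scores similarity
    strictly above the gate; None after ``max_mate_retries`` failures or for a
    singleton class. ``model`` needs only a ``forward_pair(a, b)`` method."""
    candidates = [
        im for im in ds.by_class()[anchor.class_label]
        if im.image_id != anchor.image_id
    ]
    if not candidates:
        logger.warning("class %r has no mate for %s", anchor.class_label, anchor.image_id)
        return None
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))[:cfg.max_mate_retries]
    for i in order:
        mate = candidates[i]
        s = similarity_score(model.forward_pair(anchor, mate).d)
        if s > cfg.similarity_gate:
            return mate
    return None


def heatmap_to_bbox(values: np.ndarray, cfg: RefinementConfig) -> BoundingBox:
    """Bounding box of the largest 8-connected component of the heatmap
    binarized at ``binarize_frac * max``.

    Falls back to the full image for an all-zero map or when the box covers
    less than ``min_box_frac`` of the image area.
    """
    h = np.asarray(values, dtype=np.float64)
    H, W = h.shape
    full = BoundingBox(0, 0, W, H, fallback=True)
    vmax = h.max(initial=0.0)
    if vmax <= 0:
        return full
    binary = h >= cfg.binarize_frac * vmax
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return full
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    ys, xs = np.nonzero(labels == largest)
    box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    if box.area < cfg.min_box_frac * H * W:
        return full
    return box


def _expand_to_min_side(box: BoundingBox, H: int, W: int) -> BoundingBox:
    """Grow a box symmetrically (clamped to the image) to the minimum crop side."""
    def grow(lo, hi, limit):
        span = hi - lo
        if span >= _MIN_SIDE:
            return lo, hi
        need = _MIN_SIDE - span
        lo = max(0, lo - need // 2)
        hi = min(limit, lo + _MIN_SIDE)
        lo = max(0, hi - _MIN_SIDE)
        return lo, hi

    x0, x1 = grow(box.x_min, box.x_max, W)
    y0, y1 = grow(box.y_min, box.y_max, H)
    return BoundingBox(x0, y0, x1, y1, fallback=box.fallback)


def refine_dataset(model: SiameseNetwork, train_ds: LabeledDataset,
                   cfg: RefinementConfig, seed: int,
                   explain_fn: Callable[[SiameseNetwork, ImagePair], np.ndarray] | None = None,
                   ) -> tuple[LabeledDataset, list[dict]]:
    """Crop every confidently-matched anchor to its factual heatmap box.

    ``explain_fn(model, pair) -> normalized anchor heatmap`` defaults to the
    factual Grad-CAM map of the anchor branch. Returns the refined dataset
    (same size, ids and labels as the input) and a per-image log.
    """
    if explain_fn is None:
        def explain_fn(mdl, pair):
            ha, _ = explain_pair(mdl, pair, mode="factual")
            return ha.values

    rng = np.random.default_rng(seed)
    out: list[LabeledImage] = []
    log: list[dict] = []
    for anchor in train_ds.images:
        entry: dict = {"anchor": anchor.image_id, "mate": None,
                       "similarity": None, "bbox": None, "fallback": False,
                       "cropped": False}
        mate = select_confident_mate(model, train_ds, anchor, cfg,
                                     seed=int(rng.integers(2**31)))
        if mate is None:
            out.append(anchor)
            log.append(entry)
            continue
        sim = similarity_score(model.forward_pair(anchor, mate).d)
        pair = ImagePair(a=anchor, b=mate, label=0)
        heat = explain_fn(model, pair)
        box = heatmap_to_bbox(heat, cfg)
        box = _expand_to_min_side(box, anchor.height, anchor.width)
        out.append(LabeledImage(pixels=box.crop(anchor.pixels),
                                class_label=anchor.class_label,
                                image_id=anchor.image_id))
        entry.update(mate=mate.image_id, similarity=sim,
                     bbox=[box.x_min, box.y_min, box.x_max, box.y_max],
                     fallback=box.fallback, cropped=True)
        log.append(entry)
    return LabeledDataset(out, classes=train_ds.classes), log
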