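"""Factual and counterfactual Grad-CAM heatmaps for Siamese pairs.

For a target scalar y and the activations A^k of a chosen convolutional
layer, the neuron importance weights are the spatially averaged gradients

    alpha_k = 1/Z sum_i sum_j  dy / dA^k_ij ,

and the localization map is the ReLU of their weighted combination

    L = ReLU( sum_k alpha_k A^k ).

Here the factual target is the Siamese output d itself and the counterfactual
target is 1 - d, i.e. the same computation with every gradient negated: the
factual map shows where the evidence for the model's decision lives, the
counterfactual map where the evidence that would flip it lives. Both branches
of a pair are explained from one forward/backward pass of the weight-sharing
network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize as _sk_resize

from .datasets import ImagePair, LabeledImage
from .model import SiameseNetwork

Mode = Literal["factual", "counterfactual"]


@dataclass
class ActivationStack:
    """Feature maps of one branch at the explained layer, shape (h, w, K)."""

    maps: np.ndarray
    branch: str
    layer: str

    @property
    def K(self) -> int:
        return self.maps.shape[2]


@dataclass
class GradStack:
    """Gradients of the target scalar w.r.t. the activation stack."""

    grads: np.ndarray
    target_mode: str


@dataclass
class NeuronWeights:
    """Per-map importance weights alpha_k and the spatial size Z = h*w."""

    alpha: np.ndarray
    Z: int


@dataclass
class Heatmap:
    """Saliency map with its provenance; values are nonnegative (raw) or in
    [0,1] (after normalization)."""

    values: np.ndarray
    mode: str
    branch: str
    normalized: bool = False


def capture(model: SiameseNetwork, pair: ImagePair, mode: Mode,
            target_layer: str | None = None):
    """Run the pair through the model and pull (activations, gradients) of the
    target layer for both branches.

    The factual target is the output d; the counterfactual target 1 - d is
    realized by negating the gradients. Returns
    ``((acts_a, grads_a), (acts_b, grads_b), d)``.
    """
    if mode not in ("factual", "counterfactual"):
        raise ValueError(f"mode must be factual|counterfactual, got {mode}")
    layer = target_layer or model.spec.target_layer
    xa = model.preprocess_batch([pair.a])
    xb = model.preprocess_batch([pair.b])
    fw = model.forward_pair_batch(xa, xb)
    _, act_grads = model.pair_backward(fw, dLdd=np.ones(1), want_act_grads=True)
    acts_by_branch = (fw["ca"]["acts"], fw["cb"]["acts"])
    out = []
    for branch, acts_all, grads_all in zip("ab", acts_by_branch, act_grads):
        if layer not in acts_all:
            raise ValueError(f"target layer {layer!r} not found in backbone")
        g = grads_all[layer][0]
        if mode == "counterfactual":
            g = -g
        out.append((
            ActivationStack(maps=acts_all[layer][0], branch=branch, layer=layer),
            GradStack(grads=g, target_mode=mode),
        ))
    return out[0], out[1], float(fw["d"][0])


def neuron_importance(grads: GradStack) -> NeuronWeights:
    """alpha_k = spatial mean of the gradients of map k (1/Z sum_ij g_ijk)."""
    g = grads.grads
    h, w = g.shape[:2]
    return NeuronWeights(alpha=g.mean(axis=(0, 1)), Z=h * w)


def cam(weights: NeuronWeights, acts: ActivationStack,
        mode: str = "factual") -> Heatmap:
    """Raw localization map ReLU(sum_k alpha_k A^k), shape (h, w)."""
    if weights.alpha.shape[0] != acts.K:
        raise ValueError(
            f"weight/activation K mismatch: {weights.alpha.shape[0]} vs {acts.K}"
        )
    combo = np.tensordot(acts.maps, weights.alpha, axes=([2], [0]))
    return Heatmap(values=np.maximum(combo, 0.0), mode=mode,
                   branch=acts.branch, normalized=False)


def normalize_and_resize(raw: Heatmap, size: tuple[int, int]) -> Heatmap:
    """Min-max normalize to [0,1] and bilinearly upsample to (H, W).

    Degenerate maps: a constant positive map becomes all ones; an all-zero
    map stays all zero.
    """
    v = raw.values.astype(np.float64)
    if np.any(v < 0):
        raise ValueError("raw heatmap must be nonnegative")
    vmax, vmin = v.max(initial=0.0), v.min(initial=0.0)
    if vmax == vmin:
        norm = (v > 0).astype(np.float64)
    else:
        norm = (v - vmin) / (vmax - vmin)
    if norm.shape != tuple(size):
        norm = _sk_resize(norm, size, order=1, preserve_range=True,
                          anti_aliasing=False)
    return Heatmap(values=np.clip(norm, 0.0, 1.0), mode=raw.mode,
                   branch=raw.branch, normalized=True)


def explain_pair(model: SiameseNetwork, pair: ImagePair, mode: Mode = "factual",
                 target_layer: str | None = None) -> tuple[Heatmap, Heatmap]:
    """Normalized image-resolution heatmaps for both branches of a pair."""
    (acts_a, grads_a), (acts_b, grads_b), _ = capture(model, pair, mode, target_layer)
    out = []
    for acts, grads, img in ((acts_a, grads_a, pair.a), (acts_b, grads_b, pair.b)):
        raw = cam(neuron_importance(grads), acts, mode=mode)
        out.append(normalize_and_resize(raw, (img.height, img.width)))
    return out[0], out[1]


def overlay(h: Heatmap, image: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped heatmap over an RGB image; returns uint8."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if h.values.shape != img.shape[:2]:
        raise ValueError(
            f"heatmap {h.values.shape} does not match image {img.shape[:2]}"
        )
    colored = colormaps[cmap](h.values)[:, :, :3] * 255.0
    blended = (1.0 - alpha) * img.astype(np.float64) + alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def write_explanation(model: SiameseNetwork, pair: ImagePair, out_dir: str | Path,
                      modes: tuple[Mode, ...] = ("factual", "counterfactual"),
                      alpha: float = 0.5, target_layer: str | None = None) -> dict:
    """Render overlay PNGs (per mode, per branch) plus a sidecar JSON with the
    pair ids, similarity and layer; returns the sidecar dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ida = Path(pair.a.image_id).stem
    idb = Path(pair.b.image_id).stem
    d = model.forward_pair(pair.a, pair.b).d
    files = {}
    for mode in modes:
        ha, hb = explain_pair(model, pair, mode, target_layer)
        for h, img in ((ha, pair.a), (hb, pair.b)):
            name = f"{ida}__{idb}__{mode}__{h.branch}.png"
            Image.fromarray(overlay(h, img.pixels, alpha=alpha)).save(out_dir / name)
            files[f"{mode}_{h.branch}"] = name
    sidecar = {
        "id_a": pair.a.image_id, "id_b": pair.b.image_id,
        "d": d, "s": 1.0 - d,
        "layer": target_layer or model.spec.target_layer,
        "alpha": alpha, "files": files,
    }
    with open(out_dir / f"{ida}__{idb}__explanation.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
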