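"""The Siamese verification model.

Two weight-sharing branches embed each image through a small convolutional
backbone (conv-ReLU-maxpool blocks, global average pooling, a ReLU dense
layer); the Euclidean distance between the embeddings feeds a single sigmoid
output unit, so the model output ``d`` in (0,1) behaves as a dissimilarity
score and ``s = 1 - d`` as the similarity. Training minimizes the contrastive
loss

    L = 1/2 (1 - y) Dw^2 + y max(0, m - Dw)^2

over labeled pairs (y = 0 same class, y = 1 different class). ``Dw`` is the
raw embedding distance by default — the classic formulation, where the margin
m = 2 is actually attainable; setting ``loss_input='output'`` instead feeds
the sigmoid output d to the loss, which trains far less reliably because the
margin then lies outside the sigmoid's range and the dissimilar-pair term
never vanishes. The backbone is
written in plain numpy with exact hand-derived gradients so that the same
reverse-mode machinery serves both Adam training and Grad-CAM's activation
gradients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .datasets import DatasetSplit, ImagePair, LabeledImage, build_pairs

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class BackboneSpec:
    """Architecture of the embedding backbone.

    ``target_layer`` names the ReLU-activated convolutional output used for
    explanation; the default is the last one. ``channels`` gives the output
    channels of the three conv layers (the first two are followed by 2x2 max
    pooling, the last feeds global average pooling directly), so the explained
    layer has spatial size ``input_size / 4`` and both dimensions must be
    divisible by 8 (divisible by 4 with room to pool twice).
    """

    name: str = "small-cnn"
    input_size: tuple[int, int] = (64, 64)
    channels: tuple[int, int, int] = (12, 24, 48)
    embedding_dim: int = 256
    target_layer: str = "conv3"

    def __post_init__(self) -> None:
        if self.name not in REGISTERED_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.name!r}; available: {sorted(REGISTERED_BACKBONES)}"
            )
        h, w = self.input_size
        if h % 8 or w % 8 or h < 8 or w < 8:
            raise ValueError(f"input_size must be multiples of 8, got {self.input_size}")
        if self.target_layer not in ("conv1", "conv2", "conv3"):
            raise ValueError(f"target_layer must be conv1|conv2|conv3, got {self.target_layer}")


REGISTERED_BACKBONES = {"small-cnn"}


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``margin`` is the contrastive-loss margin m; ``threshold`` the decision
    threshold on d for pair classification; ``loss_input`` selects whether the
    loss sees the raw embedding distance (default) or the sigmoid output.
    The learning rate decays linearly per epoch from its initial value to 0.
    """

    margin: float = 2.0
    threshold: float = 0.5
    learning_rate: float = 0.02
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    loss_input: Literal["output", "raw_distance"] = "raw_distance"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0,1)")
        if self.loss_input not in ("output", "raw_distance"):
            raise ValueError(f"loss_input must be output|raw_distance, got {self.loss_input}")


@dataclass(frozen=True)
class SiameseOutput:
    """Model output for one pair: dissimilarity d, similarity s = 1 - d and
    the raw (pre-head) Euclidean embedding distance."""

    d: float
    s: float
    raw_distance: float


def similarity_score(d: float) -> float:
    """Similarity of a pair given the model output d: s = 1 - d."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"model output d must lie in [0,1], got {d}")
    return 1.0 - d


def classify_pair(d: float, threshold: float) -> str:
    """'same' when d is strictly below the threshold, else 'different'."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return "same" if d < threshold else "different"


def contrastive_loss(Dw, y, m: float):
    """Contrastive pair loss: 1/2 (1-y) Dw^2 + y max(0, m - Dw)^2.

    The 1/2 factor applies to the same-class term only. Accepts scalars or
    arrays (broadcast elementwise).
    """
    Dw = np.asarray(Dw, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if m <= 0:
        raise ValueError("margin m must be positive")
    if np.any(Dw < 0):
        raise ValueError("Dw must be nonnegative")
    hinge = np.maximum(0.0, m - Dw)
    out = 0.5 * (1.0 - y) * Dw**2 + y * hinge**2
    return float(out) if out.ndim == 0 else out


def contrastive_loss_grad(Dw, y, m: float):
    """dL/dDw for the contrastive loss above."""
    Dw = np.asarray(Dw, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return (1.0 - y) * Dw - 2.0 * y * np.maximum(0.0, m - Dw)


class SiameseNetwork:
    """Weight-sharing Siamese network with a sigmoid dissimilarity head.

    ``head='distance'`` (default): d = sigmoid(w * ||eA - eB|| + b), symmetric
    by construction. ``head='absdiff'``: d = sigmoid(w . |eA - eB| + b), the
    elementwise-difference alternative.
    """

    def __init__(self, spec: BackboneSpec | None = None,
                 head: Literal["distance", "absdiff"] = "distance",
                 seed: int = 0):
        self.spec = spec or BackboneSpec()
        if head not in ("distance", "absdiff"):
            raise ValueError(f"head must be distance|absdiff, got {head}")
        self.head = head
        rng = np.random.default_rng(seed)
        c0 = 3
        c1, c2, c3 = self.spec.channels
        emb = self.spec.embedding_dim

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": he((3, 3, c0, c1), 9 * c0), "b1": np.zeros(c1),
            "W2": he((3, 3, c1, c2), 9 * c1), "b2": np.zeros(c2),
            "W3": he((3, 3, c2, c3), 9 * c2), "b3": np.zeros(c3),
            "Wd": he((c3, emb), c3), "bd": np.zeros(emb),
        }
        # b_out = -1 centers the sigmoid at unit embedding distance, the
        # midpoint of the default contrastive margin m = 2, so d < 0.5 maps to
        # "closer than half the margin" from the first epoch on.
        if head == "distance":
            self.params["w_out"] = np.array([1.0])
            self.params["b_out"] = np.array([-1.0])
        else:
            self.params["w_out"] = he((emb,), emb)
            self.params["b_out"] = np.array([-1.0])

    # ---------------------------------------------------------------- I/O

    def preprocess(self, pixels: np.ndarray) -> np.ndarray:
        """uint8 HxWxC -> float64 HxWx3 in [0,1] at the backbone input size."""
        px = np.asarray(pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.shape[2] == 1:
            px = np.repeat(px, 3, axis=2)
        x = px.astype(np.float64) / 255.0
        if x.shape[:2] != self.spec.input_size:
            x = _sk_resize(x, self.spec.input_size, order=1,
                           preserve_range=True, anti_aliasing=False)
        return x

    def preprocess_batch(self, images: Sequence[LabeledImage | np.ndarray]) -> np.ndarray:
        arrs = [
            self.preprocess(im.pixels if isinstance(im, LabeledImage) else im)
            for im in images
        ]
        return np.stack(arrs)

    # ----------------------------------------------------------- forward

    def _backbone(self, x: np.ndarray):
        p = self.params
        cache: dict = {}
        z1, cache["c1"] = nn.conv2d_forward(x, p["W1"], p["b1"])
        a1, cache["r1"] = nn.relu_forward(z1)
        p1, cache["p1"] = nn.maxpool2_forward(a1)
        z2, cache["c2"] = nn.conv2d_forward(p1, p["W2"], p["b2"])
        a2, cache["r2"] = nn.relu_forward(z2)
        p2, cache["p2"] = nn.maxpool2_forward(a2)
        z3, cache["c3"] = nn.conv2d_forward(p2, p["W3"], p["b3"])
        a3, cache["r3"] = nn.relu_forward(z3)
        g, cache["gap"] = nn.gap_forward(a3)  # (1,1) average pool straight off the last conv
        e_pre, cache["d"] = nn.dense_forward(g, p["Wd"], p["bd"])
        e, cache["re"] = nn.relu_forward(e_pre)
        cache["acts"] = {"conv1": a1, "conv2": a2, "conv3": a3}
        return e, cache

    def _backbone_backward(self, de: np.ndarray, cache: dict):
        """Backprop from the embedding; returns (param grads, grads at each
        ReLU-activated conv output)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        act_grads: dict[str, np.ndarray] = {}
        de_pre = nn.relu_backward(de, cache["re"])
        dg, grads["Wd"], grads["bd"] = nn.dense_backward(de_pre, cache["d"], p["Wd"])
        da3 = nn.gap_backward(dg, cache["gap"])
        act_grads["conv3"] = da3
        dz3 = nn.relu_backward(da3, cache["r3"])
        dp2, grads["W3"], grads["b3"] = nn.conv2d_backward(dz3, cache["c3"])
        da2 = nn.maxpool2_backward(dp2, cache["p2"])
        act_grads["conv2"] = da2
        dz2 = nn.relu_backward(da2, cache["r2"])
        dp1, grads["W2"], grads["b2"] = nn.conv2d_backward(dz2, cache["c2"])
        da1 = nn.maxpool2_backward(dp1, cache["p1"])
        act_grads["conv1"] = da1
        dz1 = nn.relu_backward(da1, cache["r1"])
        _, grads["W1"], grads["b1"] = nn.conv2d_backward(dz1, cache["c1"])
        return grads, act_grads

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Embed one preprocessed image (H,W,3) or a batch (N,H,W,3)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1:3] != self.spec.input_size:
            raise ValueError(
                f"expected input size {self.spec.input_size}, got {x.shape[1:3]}"
            )
        e, _ = self._backbone(x)
        return e[0] if single else e

    def forward_pair_batch(self, xa: np.ndarray, xb: np.ndarray) -> dict:
        """Full forward pass on a batch of preprocessed pairs.

        Returns a dict with d, raw (embedding distances), z (head pre-sigmoid),
        embeddings and the caches needed for backward.
        """
        ea, ca = self._backbone(xa)
        eb, cb = self._backbone(xb)
        diff = ea - eb
        raw = np.sqrt(np.sum(diff**2, axis=1))
        if self.head == "distance":
            z = self.params["w_out"][0] * raw + self.params["b_out"][0]
        else:
            z = np.abs(diff) @ self.params["w_out"] + self.params["b_out"][0]
        d = nn.sigmoid(np.clip(z, -30.0, 30.0))
        return {"d": d, "raw": raw, "z": z, "ea": ea, "eb": eb,
                "diff": diff, "ca": ca, "cb": cb}

    def predict_pair_batch(self, images_a: Sequence, images_b: Sequence,
                           batch_size: int = 64) -> np.ndarray:
        """Dissimilarity d for aligned sequences of images (LabeledImage or
        raw pixel arrays); batched to bound memory."""
        ds = []
        for i in range(0, len(images_a), batch_size):
            xa = self.preprocess_batch(images_a[i:i + batch_size])
            xb = self.preprocess_batch(images_b[i:i + batch_size])
            ds.append(self.forward_pair_batch(xa, xb)["d"])
        return np.concatenate(ds) if ds else np.empty(0)

    def forward_pair(self, a, b) -> SiameseOutput:
        """Score one pair of images (LabeledImage or uint8 pixel arrays)."""
        xa = self.preprocess_batch([a])
        xb = self.preprocess_batch([b])
        fw = self.forward_pair_batch(xa, xb)
        d = float(fw["d"][0])
        return SiameseOutput(d=d, s=1.0 - d, raw_distance=float(fw["raw"][0]))

    # ---------------------------------------------------------- backward

    def pair_backward(self, fw: dict, dLdd: np.ndarray | None = None,
                      dLdraw: np.ndarray | None = None,
                      want_act_grads: bool = False):
        """Backprop per-pair upstream gradients through head and both branches.

        Exactly one of ``dLdd`` (gradient w.r.t. the sigmoid output) or
        ``dLdraw`` (w.r.t. the raw distance) is given. Returns (param grads
        summed over both weight-sharing branches, act_grads) where act_grads is
        ``(branch_a, branch_b)`` dicts of gradients at each conv ReLU output
        when requested, else None.
        """
        if (dLdd is None) == (dLdraw is None):
            raise ValueError("give exactly one of dLdd or dLdraw")
        d, raw, diff = fw["d"], fw["raw"], fw["diff"]
        grads: dict[str, np.ndarray] = {}
        if dLdd is not None:
            dz = dLdd * d * (1.0 - d)
            if self.head == "distance":
                draw = dz * self.params["w_out"][0]
                grads["w_out"] = np.array([np.sum(dz * raw)])
                grads["b_out"] = np.array([np.sum(dz)])
                safe = np.maximum(raw, _EPS)
                dea = (draw / safe)[:, None] * diff
            else:
                grads["w_out"] = np.abs(diff).T @ dz
                grads["b_out"] = np.array([np.sum(dz)])
                dea = dz[:, None] * self.params["w_out"][None, :] * np.sign(diff)
        else:
            safe = np.maximum(raw, _EPS)
            dea = (dLdraw / safe)[:, None] * diff
            grads["w_out"] = np.zeros_like(self.params["w_out"])
            grads["b_out"] = np.zeros_like(self.params["b_out"])
        deb = -dea
        ga, acts_a = self._backbone_backward(dea, fw["ca"])
        gb, acts_b = self._backbone_backward(deb, fw["cb"])
        for k in ga:
            grads[k] = ga[k] + gb[k]
        return grads, (acts_a, acts_b) if want_act_grads else None

    def forward_from_target_acts(self, acts_a: np.ndarray, acts_b: np.ndarray) -> np.ndarray:
        """Recompute d from given target-layer activations (post-ReLU) of both
        branches, holding the downstream weights fixed.

        Supports the finite-difference verification of Grad-CAM's activation
        gradients. Only the default target layer (the last conv) is supported.
        """
        if self.spec.target_layer != "conv3":
            raise NotImplementedError("replay supported for the last conv layer only")
        p = self.params

        def tail(a3):
            g, _ = nn.gap_forward(a3)
            e_pre, _ = nn.dense_forward(g, p["Wd"], p["bd"])
            e, _ = nn.relu_forward(e_pre)
            return e

        ea, eb = tail(acts_a), tail(acts_b)
        diff = ea - eb
        raw = np.sqrt(np.sum(diff**2, axis=1))
        if self.head == "distance":
            z = p["w_out"][0] * raw + p["b_out"][0]
        else:
            z = np.abs(diff) @ p["w_out"] + p["b_out"][0]
        return nn.sigmoid(np.clip(z, -30.0, 30.0))

    # ---------------------------------------------------------- training

    def train(self, split: DatasetSplit, cfg: TrainConfig):
        """Train on pairs built from the split; returns (self, history).

        Pairs are constructed from ``split.train`` and ``split.val`` with the
        config seed. History is one dict per epoch with train/val loss and
        val pair accuracy; the weights with the best validation accuracy are
        retained, accuracy ties broken by the lower validation loss and then
        by the earlier epoch (small validation sets tie on accuracy often,
        and the continuous loss separates genuinely better epochs).
        """
        history: list[dict] = []
        if cfg.epochs == 0:
            return self, history
        rng = np.random.default_rng(cfg.seed)
        train_pairs = build_pairs(split.train, seed=int(rng.integers(2**31)))
        val_pairs = (
            build_pairs(split.val, seed=int(rng.integers(2**31)))
            if len(split.val) and len(split.val.by_class()) >= 2 else []
        )
        cache: dict[str, np.ndarray] = {}

        def prep(im: LabeledImage) -> np.ndarray:
            if im.image_id not in cache:
                cache[im.image_id] = self.preprocess(im.pixels)
            return cache[im.image_id]

        xa = np.stack([prep(p.a) for p in train_pairs])
        xb = np.stack([prep(p.b) for p in train_pairs])
        yv = np.array([p.label for p in train_pairs], dtype=np.float64)
        if val_pairs:
            vxa = np.stack([prep(p.a) for p in val_pairs])
            vxb = np.stack([prep(p.b) for p in val_pairs])
            vy = np.array([p.label for p in val_pairs], dtype=np.float64)

        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        best = None  # (val_accuracy, val_loss, epoch, params snapshot)
        n = len(train_pairs)
        for epoch in range(cfg.epochs):
            opt.lr = cfg.learning_rate * (1.0 - epoch / cfg.epochs)
            order = rng.permutation(n)
            total = 0.0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                fw = self.forward_pair_batch(xa[idx], xb[idx])
                Dw = fw["d"] if cfg.loss_input == "output" else fw["raw"]
                losses = contrastive_loss(Dw, yv[idx], cfg.margin)
                batch_loss = float(np.mean(losses))
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={batch_loss}"
                    )
                total += batch_loss * len(idx)
                g = contrastive_loss_grad(Dw, yv[idx], cfg.margin) / len(idx)
                if cfg.loss_input == "output":
                    grads, _ = self.pair_backward(fw, dLdd=g)
                else:
                    grads, _ = self.pair_backward(fw, dLdraw=g)
                opt.step(grads)
            rec = {"epoch": epoch, "train_loss": total / n,
                   "val_loss": float("nan"), "val_accuracy": float("nan")}
            if val_pairs:
                vd = np.concatenate([
                    self.forward_pair_batch(vxa[i:i + 64], vxb[i:i + 64])["d"]
                    for i in range(0, len(val_pairs), 64)
                ])
                vDw = vd if cfg.loss_input == "output" else None
                if vDw is None:
                    vraw = np.concatenate([
                        self.forward_pair_batch(vxa[i:i + 64], vxb[i:i + 64])["raw"]
                        for i in range(0, len(val_pairs), 64)
                    ])
                    vDw = vraw
                rec["val_loss"] = float(np.mean(contrastive_loss(vDw, vy, cfg.margin)))
                pred = (vd >= cfg.threshold).astype(int)  # 1 = different
                rec["val_accuracy"] = float(np.mean(pred == vy))
                key = (rec["val_accuracy"], -rec["val_loss"])
                if best is None or key > (best[0], -best[1]):
                    best = (rec["val_accuracy"], rec["val_loss"], epoch,
                            {k: v.copy() for k, v in self.params.items()})
            history.append(rec)
            logger.info("epoch %d: train_loss=%.4f val_acc=%.3f",
                        epoch, rec["train_loss"], rec["val_accuracy"])
        if best is not None:
            self.params.update(best[3])
        if cfg.loss_input == "raw_distance":
            self._calibrate_head(xa, xb, yv)
        return self, history

    def _calibrate_head(self, xa: np.ndarray, xb: np.ndarray, y: np.ndarray) -> None:
        """Fit the sigmoid output unit by logistic regression of the pair
        labels on the trained embedding distances (Platt scaling).

        The raw-distance contrastive loss shapes the metric but leaves the
        output unit untouched; without this step d = sigmoid(w*raw + b) keeps
        its initial scale and similarities never approach 100% however close
        the embeddings get.
        """
        from sklearn.linear_model import LogisticRegression

        feats = []
        for i in range(0, len(xa), 64):
            fw = self.forward_pair_batch(xa[i:i + 64], xb[i:i + 64])
            feats.append(fw["raw"] if self.head == "distance"
                         else np.abs(fw["diff"]))
        X = np.concatenate(feats)
        if X.ndim == 1:
            X = X[:, None]
        if len(np.unique(y)) < 2:
            return
        clf = LogisticRegression(C=10.0, max_iter=1000)
        clf.fit(X, y)  # class 1 = different, matching d
        self.params["w_out"] = clf.coef_[0].copy()
        self.params["b_out"] = np.array([float(clf.intercept_[0])])

    # -------------------------------------------------------- checkpoint

    def save(self, path: str | Path, train_config: TrainConfig | None = None) -> None:
        """Write weights plus architecture (and optional training config) to
        a single .npz checkpoint."""
        meta = {"spec": asdict(self.spec), "head": self.head,
                "train_config": asdict(train_config) if train_config else None}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SiameseNetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            spec_d = meta["spec"]
            spec_d["input_size"] = tuple(spec_d["input_size"])
            spec_d["channels"] = tuple(spec_d["channels"])
            model = cls(BackboneSpec(**spec_d), head=meta["head"])
            for k in model.params:
                model.params[k] = data[k]
        return model


def save_history(history: list[dict], path: str | Path) -> None:
    """Training history as JSON lines (epoch, train_loss, val_loss, val_accuracy)."""
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec) + "\n")
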