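"""Pair-verification metrics: accuracy, ROC AUC, precision and recall.

The positive class for reporting is "similar" (pair label 0); a pair is
predicted similar when the model output d falls strictly below the decision
threshold. Precision and recall are macro-averages over the similar and
dissimilar classes, with the per-class values retained so either convention
can be reconstructed. AUC scores the similar class by s = 1 - d and follows
the Mann-Whitney convention (ties count one half).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from .datasets import ImagePair

logger = logging.getLogger(__name__)


@dataclass
class PairMetrics:
    accuracy: float
    auc: float
    precision: float
    recall: float
    n_similar: int
    n_dissimilar: int
    threshold: float
    per_class: dict
    confusion: dict  # similar treated as positive: tp, fp, fn, tn

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def evaluate_scores(d: np.ndarray, labels: np.ndarray, threshold: float) -> PairMetrics:
    """Metrics from model outputs d and pair labels (0 similar, 1 dissimilar)."""
    d = np.asarray(d, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if d.size == 0:
        raise ValueError("no pairs to evaluate")
    pred = (d >= threshold).astype(int)  # 1 = predicted different
    accuracy = float(np.mean(pred == labels))
    # per-class precision/recall over {similar=0, dissimilar=1}
    prec = precision_score(labels, pred, labels=[0, 1], average=None,
                           zero_division=0.0)
    rec = recall_score(labels, pred, labels=[0, 1], average=None,
                       zero_division=0.0)
    per_class = {
        "similar": {"precision": float(prec[0]), "recall": float(rec[0])},
        "dissimilar": {"precision": float(prec[1]), "recall": float(rec[1])},
    }
    if len(np.unique(labels)) < 2:
        logger.warning("single-label pair set: AUC undefined")
        auc = math.nan
    else:
        auc = float(roc_auc_score(labels == 0, 1.0 - d))
    tp = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 0) & (labels == 1)))
    fn = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 1) & (labels == 1)))
    return PairMetrics(
        accuracy=accuracy,
        auc=auc,
        precision=float(np.mean(prec)),
        recall=float(np.mean(rec)),
        n_similar=int(np.sum(labels == 0)),
        n_dissimilar=int(np.sum(labels == 1)),
        threshold=threshold,
        per_class=per_class,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def evaluate_pairs(model, pairs: Sequence[ImagePair], threshold: float) -> PairMetrics:
    """Score every pair with the model, then compute verification metrics."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    d = model.predict_pair_batch([p.a for p in pairs], [p.b for p in pairs])
    labels = np.array([p.label for p in pairs], dtype=int)
    return evaluate_scores(d, labels, threshold)


def write_per_pair_csv(pairs: Sequence[ImagePair], d: np.ndarray,
                       threshold: float, path: str | Path) -> None:
    """Per-pair breakdown: id_a, id_b, label, d, s, prediction."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "label", "d", "s", "prediction"])
        for p, di in zip(pairs, d):
            pred = "same" if di < threshold else "different"
            writer.writerow([p.a.image_id, p.b.image_id, p.label,
                             f"{di:.6f}", f"{1 - di:.6f}", pred])
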