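"""Flat run configuration shared by the CLI commands.

A config file is a flat YAML mapping; command-line flags override file
values, and every run writes its resolved configuration (including the seed)
beside its outputs so it can be reproduced bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .model import BackboneSpec, TrainConfig
from .refine import RefinementConfig
from .synth import SyntheticSpec


@dataclass
class RunConfig:
    # paths
    data_root: str | None = None
    output_dir: str = "simexplain_out"
    checkpoint: str | None = None
    # splitting
    test_frac: float = 0.2
    val_frac: float = 0.1
    # training
    margin: float = 2.0
    threshold: float = 0.5
    learning_rate: float = 0.02
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    loss_input: str = "raw_distance"
    # backbone
    backbone: str = "small-cnn"
    input_size: tuple[int, int] = (64, 64)
    embedding_dim: int = 256
    target_layer: str = "conv3"
    head: str = "distance"
    # synthetic data
    n_classes: int = 5
    n_per_class: int = 40
    image_size: tuple[int, int] = (64, 64)
    shape_size_min: int = 16
    shape_size_max: int = 28
    noise_level: float = 0.25
    # refinement
    similarity_gate: float = 0.80
    binarize_frac: float = 0.5
    max_mate_retries: int = 5
    min_box_frac: float = 0.01
    # explanation
    mode: str = "factual"
    alpha: float = 0.5

    @classmethod
    def from_file(cls, path: str | Path | None, overrides: dict | None = None) -> "RunConfig":
        """Load a flat YAML config; unknown keys are rejected. ``overrides``
        (e.g. from CLI flags) take precedence over file values."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must be a flat mapping")
            values.update(loaded)
        values.update({k: v for k, v in (overrides or {}).items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("input_size", "image_size"):
            if key in values:
                values[key] = tuple(values[key])
        return cls(**values)

    def write_resolved(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.yaml"
        payload = asdict(self)
        payload["input_size"] = list(self.input_size)
        payload["image_size"] = list(self.image_size)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    # ---- views onto the module-level configs

    def backbone_spec(self) -> BackboneSpec:
        return BackboneSpec(name=self.backbone, input_size=tuple(self.input_size),
                            embedding_dim=self.embedding_dim,
                            target_layer=self.target_layer)

    def train_config(self) -> TrainConfig:
        return TrainConfig(margin=self.margin, threshold=self.threshold,
                           learning_rate=self.learning_rate, epochs=self.epochs,
                           batch_size=self.batch_size, seed=self.seed,
                           loss_input=self.loss_input)

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(n_classes=self.n_classes, n_per_class=self.n_per_class,
                             image_size=tuple(self.image_size),
                             shape_size_range=(self.shape_size_min, self.shape_size_max),
                             noise_level=self.noise_level, seed=self.seed)

    def refinement_config(self) -> RefinementConfig:
        return RefinementConfig(similarity_gate=self.similarity_gate,
                                binarize_frac=self.binarize_frac,
                                max_mate_retries=self.max_mate_retries,
                                min_box_frac=self.min_box_frac)
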