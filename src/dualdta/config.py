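"""YAML (de)serialization of model and training configuration.

Layout::

    model:
      encoder: {embed_dim: 128, lstm_layers: 2, heads: 8, ...}
      gnn: {n_layers: 3, hidden_dim: 128, mlp_depth: 2, variant: paper_eq16}
      head_hidden: 256
      use_gem: true
      ...
    train:
      warmup_epochs: 20
      joint_epochs: 200
      lr: 0.001
      batch_size: 128
      seed: 0
      patience: 20
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig


def load_config(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model_cfg = ModelConfig.from_dict(raw.get("model", {}))
    train_cfg = TrainConfig(**raw.get("train", {}))
    return model_cfg, train_cfg


def save_config(
    model_cfg: ModelConfig, train_cfg: TrainConfig, path: str | Path
) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {"model": model_cfg.to_dict(), "train": asdict(train_cfg)},
            sort_keys=False,
        )
    )
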