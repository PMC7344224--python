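"""One YAML configuration tying the pipeline together.

Top-level keys: ``preprocess``, ``augment``, ``model``, ``train``,
``phantom``, ``eval``. Every key is optional; omitted values fall back to
the defaults of the corresponding dataclasses (which are the full-scale
protocol: 1.25 x 1.25 mm target spacing, 256 x 256 crop, all four
augmentations on, base_filters 64, batch 20, lr 0.001 halved every 50
epochs, dropout 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .augment import AugmentConfig
from .preprocess import PreprocessConfig
from .train import TrainConfig
from .types import ValidationError
from .unet import UNetConfig


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    phantom: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)


def _preprocess_from(d: dict) -> PreprocessConfig:
    kw = {}
    if "target_spacing" in d:
        kw["target_spacing_mm"] = tuple(d["target_spacing"])
    if "crop_size" in d:
        c = d["crop_size"]
        kw["crop_size"] = (c, c) if isinstance(c, int) else tuple(c)
    if "resample" in d:
        kw["resample_enabled"] = bool(d["resample"])
    return PreprocessConfig(**kw)


def _augment_from(d: dict) -> AugmentConfig:
    kw = {}
    for yaml_key, attr in (("flip", "flip_enabled"), ("rotation", "rotation_enabled"),
                           ("scale", "scale_enabled"), ("crop_shift", "crop_shift_enabled"),
                           ("gamma", "gamma_enabled")):
        if yaml_key in d:
            kw[attr] = bool(d[yaml_key])
    for yaml_key, attr in (("rotation_range", "rotation_range_deg"),
                           ("scale_range", "scale_range"),
                           ("gamma_range", "gamma_range")):
        if yaml_key in d:
            kw[attr] = tuple(d[yaml_key])
    return AugmentConfig(**kw)


def _model_from(d: dict) -> UNetConfig:
    kw = {}
    if "base_filters" in d:
        kw["base_filters"] = int(d["base_filters"])
    if "dropout" in d:
        kw["dropout_rate"] = float(d["dropout"])
    return UNetConfig(**kw)


def _train_from(d: dict) -> TrainConfig:
    kw = {}
    for yaml_key, attr in (("batch_size", "batch_size"), ("lr", "initial_lr"),
                           ("lr_decay_factor", "lr_decay_factor"),
                           ("lr_decay_every", "lr_decay_every"),
                           ("momentum", "momentum"),
                           ("epochs", "epochs"), ("seed", "seed")):
        if yaml_key in d:
            kw[attr] = type(getattr(TrainConfig(), attr))(d[yaml_key])
    return TrainConfig(**kw)


def load_config(source=None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file path, a dict, or nothing."""
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    return PipelineConfig(
        preprocess=_preprocess_from(data.get("preprocess", {})),
        augment=_augment_from(data.get("augment", {})),
        model=_model_from(data.get("model", {})),
        train=_train_from(data.get("train", {})),
        phantom=dict(data.get("phantom", {})),
        eval=dict(data.get("eval", {})),
    )


def dump_config(config: PipelineConfig) -> str:
    """Serialize the resolved config back to YAML (for run logs)."""
    data = {
        "preprocess": {
            "target_spacing": list(config.preprocess.target_spacing_mm),
            "crop_size": list(config.preprocess.crop_size),
            "resample": config.preprocess.resample_enabled,
        },
        "augment": {
            "flip": config.augment.flip_enabled,
            "rotation": config.augment.rotation_enabled,
            "rotation_range": list(config.augment.rotation_range_deg),
            "scale": config.augment.scale_enabled,
            "scale_range": list(config.augment.scale_range),
            "crop_shift": config.augment.crop_shift_enabled,
            "gamma": config.augment.gamma_enabled,
        },
        "model": {
            "base_filters": config.model.base_filters,
            "dropout": config.model.dropout_rate,
        },
        "train": {
            "batch_size": config.train.batch_size,
            "lr": config.train.initial_lr,
            "lr_decay_factor": config.train.lr_decay_factor,
            "lr_decay_every": config.train.lr_decay_every,
            "momentum": config.train.momentum,
            "epochs": config.train.epochs,
            "seed": config.train.seed,
        },
        "phantom": config.phantom,
        "eval": config.eval,
    }
    return yaml.safe_dump(data, sort_keys=False)
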