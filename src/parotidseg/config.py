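"""YAML configuration: one file with data / model / train / augmentation
sections mapped onto the package's config dataclasses."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .augment import AffineParams, AugmentConfig
from .model import ModelConfig
from .train import TrainConfig

DEFAULT_DATA = {
    "input_size": 512,
    "sequences": ["T1w", "T2w", "T1wC"],
    "normalization": {"mode": "minmax_volume"},
    "laterality_axis": "col",
}


def default_config() -> dict:
    """All sections at their defaults (paper-stated constants included)."""
    return {
        "data": dict(DEFAULT_DATA),
        "model": ModelConfig(),
        "train": TrainConfig(),
        "augmentation": AugmentConfig(),
    }


def load_config(path=None) -> dict:
    """Load a YAML config; missing sections/keys fall back to defaults.

    ``augmentation: null`` (or ``augmentation: {enabled: false}``) disables
    augmentation: the section maps to None.
    """
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    data = dict(DEFAULT_DATA)
    data.update(doc.get("data") or {})
    model_kwargs = dict(doc.get("model") or {})
    model_kwargs.setdefault("input_size", data["input_size"])
    data["input_size"] = model_kwargs["input_size"]
    model = ModelConfig(**model_kwargs)
    train = TrainConfig(**(doc.get("train") or {}))
    if "augmentation" in doc and doc["augmentation"] is None:
        augmentation = None
    else:
        aug_kwargs = dict(doc.get("augmentation") or {})
        if aug_kwargs.pop("enabled", True) is False:
            augmentation = None
        else:
            affine = aug_kwargs.pop("affine_params", None)
            if isinstance(affine, dict):
                aug_kwargs["affine_params"] = AffineParams(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in affine.items()
                })
            for key in ("gray_scale_range", "gray_shift_range"):
                if key in aug_kwargs:
                    aug_kwargs[key] = tuple(aug_kwargs[key])
            augmentation = AugmentConfig(**aug_kwargs)
    return {"data": data, "model": model, "train": train,
            "augmentation": augmentation}


def dump_config(config: dict, path):
    """Write a config dict (as produced by load/default) back to YAML."""
    doc = {
        "data": config["data"],
        "model": asdict(config["model"]),
        "train": asdict(config["train"]),
        "augmentation": (
            None if config["augmentation"] is None else asdict(config["augmentation"])
        ),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
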