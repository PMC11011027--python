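"""YAML configuration: a flat file describing the network and schedule.

Example::

    backbone: {profile: desk, pretrained: false, extra_stem_pool: true}
    ifpm: {merge: sum}
    laem: {pool_position: pre, shared_weights: true, reduction: 16, kernel: 7}
    model: {use_ifpm: true, use_laem: true}
    eval: {feature: concat}
    train: {lr_base: 0.002, lr_classifier: 0.02, epochs: 150, seed: 0}
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .reid_net import TrainConfig

__all__ = ["load_config", "net_kwargs_from_config", "train_config_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def net_kwargs_from_config(cfg: dict) -> dict:
    """Translate the nested YAML sections into SerialReIDNet keyword args."""
    bb = cfg.get("backbone", {})
    ifpm = cfg.get("ifpm", {})
    laem = cfg.get("laem", {})
    model = cfg.get("model", {})
    ev = cfg.get("eval", {})
    out: dict = {}
    if "profile" in bb:
        out["profile"] = bb["profile"]
    if "extra_stem_pool" in bb:
        out["extra_stem_pool"] = bb["extra_stem_pool"]
    if bb.get("pretrained"):
        raise RuntimeError("pretrained backbones require an explicit weights "
                           "file; set backbone.weights and load it yourself")
    if "merge" in ifpm:
        out["merge"] = ifpm["merge"]
    for src, dst in (("reduction", "reduction"), ("kernel", "spatial_kernel"),
                     ("shared_weights", "shared_weights"),
                     ("pool_position", "pool_position"),
                     ("n_blocks", "n_blocks")):
        if src in laem:
            out[dst] = laem[src]
    for key in ("use_ifpm", "use_laem"):
        if key in model:
            out[key] = model[key]
    if "feature" in ev:
        out["feature"] = ev["feature"]
    return out


def train_config_from_config(cfg: dict) -> TrainConfig:
    section = cfg.get("train", {})
    valid = {f.name for f in fields(TrainConfig)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown train config keys: {sorted(unknown)}")
    if "erasing_area" in section:
        section = dict(section, erasing_area=tuple(section["erasing_area"]))
    return TrainConfig(**section)
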