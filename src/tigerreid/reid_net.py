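"""Serial dual-branch re-identification network, training and results.

The descriptor extractor chains backbone -> inverted-pyramid global
fusion -> local dual-domain attention in series: the global branch's
un-pooled fused map is the local branch's input.  The pooled global
vector F_Global and the concatenated part vectors F_Local (equal length)
are concatenated into the retrieval descriptor and fed to a single linear
classifier over identity classes; training minimises softmax
cross-entropy over identities.

The public modelling surface follows the model/results idiom:
:class:`ReIDModel` is built from data (directly or via
:meth:`ReIDModel.from_manifest`), its :meth:`~ReIDModel.fit` runs the
SGD schedule (two parameter groups — the classifier at 10x the base
learning rate — with a single step decay) and returns a
:class:`ReIDResults` carrying the fitted weights, the per-epoch history
and retrieval evaluation helpers.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import autograd as ag
from . import eval_retrieval as er
from . import synthetic_data as sd
from .autograd import Tensor
from .backbone import PROFILES, ResNetBackbone, build_backbone
from .global_fusion import InvertedPyramid
from .local_attention import LocalBranch
from .nn import Linear, Module, SGD

__all__ = [
    "Descriptor",
    "ClassOutput",
    "TrainConfig",
    "SerialReIDNet",
    "cross_entropy",
    "make_optimizer",
    "lr_at_epoch",
    "set_epoch_lr",
    "ReIDModel",
    "ReIDResults",
]

IMAGE_MEAN = 0.5
IMAGE_STD = 0.5


@dataclass
class Descriptor:
    """Branch outputs and their concatenation, per image in the batch."""

    f_global: np.ndarray               # (B, C)
    f_local: np.ndarray | None         # (B, C) or None when the branch is off
    concat: np.ndarray                 # (B, C) or (B, 2C)


@dataclass
class ClassOutput:
    logits: np.ndarray                 # (B, K)
    probs: np.ndarray                  # (B, K), rows sum to 1
    n_classes: int


def cross_entropy(probs, y) -> float:
    """-sum_c y_c log p_c with a one-hot target; log clamped at 1e-12."""
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(y, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"probs shape {p.shape} != target shape {t.shape}")
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -(t * logp).sum(axis=-1)
    return float(loss.mean())


@dataclass
class TrainConfig:
    """SGD schedule: base lr for the feature extractor, 10x for the
    classifier, one step decay, momentum and weight decay throughout."""

    lr_base: float = 0.002
    lr_classifier: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 16
    epochs: int = 150
    lr_decay_epoch: int = 100
    lr_decay_factor: float = 0.1
    seed: int = 0
    rotation_max_deg: float = 15.0
    erasing_area: tuple[float, float] = (0.02, 0.2)
    augment_prob: float = 0.5

    def __post_init__(self):
        for name in ("lr_base", "lr_classifier", "batch_size", "epochs",
                     "lr_decay_factor"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("momentum", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.lr_decay_epoch < self.epochs:
            raise ValueError("lr_decay_epoch must be smaller than epochs")


class SerialReIDNet(Module):
    """backbone -> IFPM -> LAEM in series, plus the linear classifier.

    ``use_ifpm`` / ``use_laem`` switch the two branches off for ablation:
    with both off the descriptor is the average-pooled C4 map.
    """

    def __init__(self, num_classes: int, profile: str = "desk",
                 use_ifpm: bool = True, use_laem: bool = True,
                 extra_stem_pool: bool = True, merge: str = "sum",
                 n_blocks: int = 4, reduction: int = 16, spatial_kernel: int = 7,
                 shared_weights: bool = True, pool_position: str = "pre",
                 feature: str = "concat", seed: int = 0):
        super().__init__()
        if num_classes is None or num_classes < 1:
            raise ValueError("num_classes must be a positive integer")
        if feature not in ("concat", "global", "local"):
            raise ValueError(f"unknown retrieval feature {feature!r}")
        if feature == "local" and not use_laem:
            raise ValueError("feature='local' requires use_laem=True")
        self.backbone = build_backbone(profile, extra_stem_pool=extra_stem_pool,
                                       seed=seed)
        widths = PROFILES[profile].widths
        c4 = widths[3]
        self.use_ifpm = use_ifpm
        self.use_laem = use_laem
        self.feature = feature
        self.num_classes = num_classes
        self.profile = profile
        if use_ifpm:
            self.ifpm = InvertedPyramid(widths, merge=merge, seed=seed + 1)
        if use_laem:
            self.laem = LocalBranch(c4, n_blocks=n_blocks, reduction=reduction,
                                    kernel=spatial_kernel,
                                    shared_weights=shared_weights,
                                    pool_position=pool_position, seed=seed + 2)
        self.descriptor_dim = 2 * c4 if use_laem else c4
        rng = np.random.default_rng(seed + 3)
        self.classifier = Linear(self.descriptor_dim, num_classes,
                                 bias=True, std=0.01, rng=rng)

    def forward_tensors(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Graph-building forward: (descriptor tensor, logits tensor)."""
        stages = self.backbone(x)
        if self.use_ifpm:
            pyr = self.ifpm(stages)
            f_global, fused = pyr.f_global, pyr.fused_map
        else:
            f_global = ag.global_avg_pool2d(stages.c4)
            fused = stages.c4
        parts = [f_global]
        if self.use_laem:
            parts.append(self.laem(fused).f_local)
        desc = parts[0] if len(parts) == 1 else ag.concat(parts, axis=1)
        return desc, self.classifier(desc)

    def forward(self, batch) -> tuple[Descriptor, ClassOutput]:
        """Numpy-facing forward returning descriptor and class output."""
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        desc, logits = self.forward_tensors(x)
        c4 = self.descriptor_dim // (2 if self.use_laem else 1)
        f_global = desc.data[:, :c4]
        f_local = desc.data[:, c4:] if self.use_laem else None
        probs = ag.softmax(logits.data.astype(np.float64), axis=1)
        return (Descriptor(f_global, f_local, desc.data),
                ClassOutput(logits.data, probs, self.num_classes))

    def extract(self, batch) -> np.ndarray:
        """Retrieval descriptors (eval mode, no graph)."""
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                desc, _ = self.forward(batch)
        finally:
            self.train(was_training)
        if self.feature == "global":
            return desc.f_global
        if self.feature == "local":
            return desc.f_local
        return desc.concat


def make_optimizer(cfg: TrainConfig, model: SerialReIDNet) -> SGD:
    """SGD with two parameter groups: classifier vs. everything else."""
    cls_params = set(id(p) for p in model.classifier.parameters())
    base = [p for p in model.parameters() if id(p) not in cls_params]
    head = model.classifier.parameters()
    return SGD([{"params": base, "lr": cfg.lr_base},
                {"params": head, "lr": cfg.lr_classifier}],
               momentum=cfg.momentum, weight_decay=cfg.weight_decay)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> tuple[float, float]:
    """(base lr, classifier lr) in force during ``epoch`` (0-based)."""
    f = cfg.lr_decay_factor if epoch >= cfg.lr_decay_epoch else 1.0
    return cfg.lr_base * f, cfg.lr_classifier * f


def set_epoch_lr(optimizer: SGD, cfg: TrainConfig, epoch: int) -> None:
    base, head = lr_at_epoch(cfg, epoch)
    optimizer.param_groups[0]["lr"] = base
    optimizer.param_groups[1]["lr"] = head


def normalize_images(images: np.ndarray) -> np.ndarray:
    """(N,H,W,3) in [0,1] -> normalised (N,3,H,W) float32."""
    x = (np.asarray(images, dtype=np.float32) - IMAGE_MEAN) / IMAGE_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ReIDModel:
    """Re-identification model bound to a labelled image collection.

    Parameters
    ----------
    images : (N, H, W, 3) float array in [0, 1]
    labels : (N,) integer identity labels, contiguous in [0, K)
    split : (N,) array of "train" / "val"
    config : TrainConfig, the optimisation schedule
    **net_kwargs : forwarded to :class:`SerialReIDNet` (profile, branch
        switches, attention settings, ...)
    """

    def __init__(self, images, labels, split, config: TrainConfig | None = None,
                 **net_kwargs):
        images = np.asarray(images, dtype=np.float32)
        labels = np.asarray(labels)
        split = np.asarray(split)
        if len(images) == 0:
            raise ValueError("empty dataset")
        if not (len(images) == len(labels) == len(split)):
            raise ValueError("images, labels and split lengths disagree")
        self.config = config or TrainConfig()
        classes = np.unique(labels)
        n_classes = int(classes.max()) + 1
        if classes.min() < 0:
            raise ValueError("labels must be non-negative")
        train_mask = split == "train"
        val_mask = split == "val"
        if not train_mask.any():
            raise ValueError("no training images in the split")
        train_classes = set(np.unique(labels[train_mask]).tolist())
        missing = set(np.unique(labels[val_mask]).tolist()) - train_classes
        if missing:
            raise ValueError(f"validation identities {sorted(missing)} never "
                             "appear in the training split")
        self.images, self.labels, self.split = images, labels, split
        self.train_idx = np.flatnonzero(train_mask)
        self.val_idx = np.flatnonzero(val_mask)
        # retrieval on the val pool needs at least one identity with >= 2 images
        val_counts = np.bincount(labels[val_mask].astype(int),
                                 minlength=n_classes) if val_mask.any() else None
        self.val_evaluable = bool(val_counts is not None and val_counts.max() >= 2)
        self.net = SerialReIDNet(num_classes=n_classes,
                                 seed=self.config.seed, **net_kwargs)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dataset(cls, dataset: sd.SyntheticDataset,
                     config: TrainConfig | None = None, **net_kwargs) -> "ReIDModel":
        return cls(dataset.images, dataset.labels,
                   dataset.manifest["split"].to_numpy(), config=config,
                   **net_kwargs)

    @classmethod
    def from_manifest(cls, manifest_path, images_root=None,
                      config: TrainConfig | None = None, **net_kwargs) -> "ReIDModel":
        """Build from a CSV manifest with columns path, entity_id, split."""
        from PIL import Image
        manifest = pd.read_csv(manifest_path)
        for col in ("path", "entity_id", "split"):
            if col not in manifest.columns:
                raise ValueError(f"manifest is missing the {col!r} column")
        root = Path(images_root) if images_root else Path(manifest_path).parent
        imgs = []
        for p in manifest["path"]:
            with Image.open(root / p) as im:
                imgs.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
        return cls(np.stack(imgs), manifest["entity_id"].to_numpy(),
                   manifest["split"].to_numpy(), config=config, **net_kwargs)

    # -- training ------------------------------------------------------------
    def _augment(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        if rng.uniform() < cfg.augment_prob:
            img = sd.random_rotation(img, cfg.rotation_max_deg,
                                     seed=rng.integers(2**31 - 1))
        if rng.uniform() < cfg.augment_prob:
            img = sd.random_erasing(img, cfg.erasing_area,
                                    seed=rng.integers(2**31 - 1))
        return img

    def fit(self, epochs: int | None = None, eval_every: int = 1,
            log_path=None, verbose: bool = False) -> "ReIDResults":
        """Run the training schedule; returns the fitted results object.

        Augmentation (random rotation + random erasing, each with its own
        coin flip per image) is applied to the training split only.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        net = self.net
        opt = make_optimizer(cfg, net)
        rng = np.random.default_rng(cfg.seed)
        history: list[dict] = []
        log_file = open(log_path, "w") if log_path else None
        try:
            for epoch in range(epochs):
                set_epoch_lr(opt, cfg, epoch)
                net.train()
                order = rng.permutation(self.train_idx)
                losses, correct, seen = [], 0, 0
                for start in range(0, len(order), cfg.batch_size):
                    idx = order[start:start + cfg.batch_size]
                    batch = np.stack([self._augment(self.images[i], rng)
                                      for i in idx])
                    x = Tensor(normalize_images(batch))
                    y = self.labels[idx].astype(np.int64)
                    _, logits = net.forward_tensors(x)
                    loss = ag.softmax_cross_entropy(logits, y)
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    losses.append(loss.item())
                    correct += int((logits.data.argmax(axis=1) == y).sum())
                    seen += len(idx)
                row = {"epoch": epoch, "loss": float(np.mean(losses)),
                       "train_acc": correct / max(seen, 1),
                       "lr_base": lr_at_epoch(cfg, epoch)[0],
                       "lr_classifier": lr_at_epoch(cfg, epoch)[1],
                       "val_rank1": np.nan, "val_mAP": np.nan}
                if self.val_evaluable and (epoch % eval_every == 0
                                           or epoch == epochs - 1):
                    report = self._evaluate_split(self.val_idx)
                    row["val_rank1"] = report.rank1
                    row["val_mAP"] = report.mAP
                history.append(row)
                if log_file:
                    log_file.write(json.dumps(row) + "\n")
                    log_file.flush()
                if verbose:
                    print(f"epoch {epoch:3d}  loss {row['loss']:.4f}  "
                          f"train_acc {row['train_acc']:.3f}  "
                          f"val_rank1 {row['val_rank1']:.3f}")
        finally:
            if log_file:
                log_file.close()
        return ReIDResults(self, pd.DataFrame(history))

    # -- evaluation ----------------------------------------------------------
    def _evaluate_split(self, idx: np.ndarray) -> er.EvalReport:
        descs = []
        for start in range(0, len(idx), self.config.batch_size):
            batch = normalize_images(self.images[idx[start:start + self.config.batch_size]])
            descs.append(self.net.extract(batch))
        return er.evaluate_descriptors(np.concatenate(descs, axis=0),
                                       self.labels[idx], list(idx))


class ReIDResults:
    """Fitted model: weights, per-epoch history, evaluation and export."""

    def __init__(self, model: ReIDModel, history: pd.DataFrame):
        self.model = model
        self.history = history
        self.state = model.net.state_dict()

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    @property
    def val_rank1(self) -> float:
        vals = self.history["val_rank1"].dropna()
        return float(vals.iloc[-1]) if len(vals) else float("nan")

    def evaluate(self, split: str = "val") -> er.EvalReport:
        """Single-pool retrieval evaluation of one split."""
        idx = {"val": self.model.val_idx, "train": self.model.train_idx}.get(split)
        if idx is None:
            raise ValueError(f"unknown split {split!r}")
        return self.model._evaluate_split(idx)

    def extract(self, images: np.ndarray) -> np.ndarray:
        """Descriptors for new images ((N,H,W,3) in [0,1])."""
        return self.model.net.extract(normalize_images(images))

    def save(self, path) -> None:
        np.savez(path, **self.state)

    def summary(self) -> str:
        m = self.model
        cfg = m.config
        lines = [
            "Serial multi-scale re-identification network",
            "=" * 52,
            f"profile: {m.net.profile}   classes: {m.net.num_classes}   "
            f"descriptor dim: {m.net.descriptor_dim}",
            f"branches: IFPM={'on' if m.net.use_ifpm else 'off'}  "
            f"LAEM={'on' if m.net.use_laem else 'off'}  "
            f"retrieval feature: {m.net.feature}",
            f"train images: {len(m.train_idx)}   val images: {len(m.val_idx)}",
            f"schedule: SGD lr {cfg.lr_base}/{cfg.lr_classifier} (x{cfg.lr_decay_factor} "
            f"at epoch {cfg.lr_decay_epoch}), momentum {cfg.momentum}, "
            f"weight decay {cfg.weight_decay}, batch {cfg.batch_size}",
            f"epochs run: {len(self.history)}   final loss: {self.final_loss:.4f}",
        ]
        vals = self.history["val_rank1"].dropna()
        if len(vals):
            last = self.history.dropna(subset=["val_rank1"]).iloc[-1]
            lines.append(f"val Rank-1: {last['val_rank1']:.4f}   "
                         f"val mAP: {last['val_mAP']:.4f}")
        return "\n".join(lines)
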