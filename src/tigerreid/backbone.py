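"""Stage-wise residual backbone for striped-animal re-identification.

The descriptor network consumes four stage outputs C1..C4 of a residual
feature extractor.  Two profiles are provided:

``full``
    A 50-layer bottleneck design (stage depths 3/4/6/3, stage channel
    widths 256/512/1024/2048).  The stem down-samples by 8 — one stride-2
    pooling more than the textbook design — so that a 256x512 input yields
    C1 of 32x64 and C4 of 8x16; the extra pooling can be disabled with
    ``extra_stem_pool=False``.  The final stage's entry stride is 1
    (its down-sampling is removed), so stages 3 and 4 share spatial size
    and the deepest features keep a usable resolution for part-based
    processing.

``desk``
    A reduced variant (basic blocks, depths 2/2/2/2, widths divided by 8)
    with the identical stride pattern, suitable for CPU training in
    minutes while preserving every downstream shape relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential

__all__ = [
    "StageFeatures",
    "BackboneProfile",
    "PROFILES",
    "ResNetBackbone",
    "build_backbone",
    "extract_stages",
]


@dataclass
class StageFeatures:
    """The four stage maps C1..C4 feeding the pyramid fusion."""

    c1: Tensor
    c2: Tensor
    c3: Tensor
    c4: Tensor

    def as_tuple(self) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        return (self.c1, self.c2, self.c3, self.c4)

    @property
    def channels(self) -> tuple[int, int, int, int]:
        return tuple(t.shape[1] for t in self.as_tuple())


@dataclass(frozen=True)
class BackboneProfile:
    name: str
    block: str                      # "bottleneck" | "basic"
    depths: tuple[int, int, int, int]
    widths: tuple[int, int, int, int]
    stem_width: int


PROFILES: dict[str, BackboneProfile] = {
    "full": BackboneProfile("full", "bottleneck", (3, 4, 6, 3),
                            (256, 512, 1024, 2048), 64),
    "desk": BackboneProfile("desk", "basic", (2, 2, 2, 2),
                            (32, 64, 128, 256), 32),
}

# entry stride per stage; the last stage keeps stride 1 (down-sampling removed)
_STAGE_STRIDES = (1, 2, 2, 1)


class BasicBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch))
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return ag.relu(ag.add(out, sc))


class Bottleneck(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand (x4), as in 50-layer residual nets."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        mid = out_ch // 4
        self.conv1 = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch))
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = ag.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return ag.relu(ag.add(out, sc))


class ResNetBackbone(Module):
    """Residual extractor exposing all four stage maps."""

    def __init__(self, profile: BackboneProfile, extra_stem_pool: bool = True,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.profile = profile
        self.extra_stem_pool = extra_stem_pool
        # total spatial reduction before stage 1: conv/2, pool/2 (, pool/2)
        self.stem_stride = 8 if extra_stem_pool else 4
        self.total_stride = self.stem_stride * 4   # stages 2 and 3 halve again
        self.stem_conv = Conv2d(3, profile.stem_width, 7, stride=2, padding=3,
                                bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(profile.stem_width)
        block_cls = Bottleneck if profile.block == "bottleneck" else BasicBlock
        in_ch = profile.stem_width
        for i, (depth, width, stride) in enumerate(
                zip(profile.depths, profile.widths, _STAGE_STRIDES)):
            blocks = []
            for j in range(depth):
                blocks.append(block_cls(in_ch, width, stride if j == 0 else 1, rng))
                in_ch = width
            setattr(self, f"stage{i + 1}", Sequential(*blocks))

    def forward(self, x: Tensor) -> StageFeatures:
        self.validate_input(x.shape)
        out = ag.relu(self.stem_bn(self.stem_conv(x)))
        out = ag.max_pool2d(out, 3, 2, 1)
        if self.extra_stem_pool:
            out = ag.max_pool2d(out, 3, 2, 1)
        c1 = self.stage1(out)
        c2 = self.stage2(c1)
        c3 = self.stage3(c2)
        c4 = self.stage4(c3)
        return StageFeatures(c1, c2, c3, c4)

    def validate_input(self, shape: tuple[int, ...]) -> None:
        if len(shape) != 4 or shape[1] != 3:
            raise ValueError(f"expected a B x 3 x H x W batch, got {shape}")
        _, _, h, w = shape
        s = self.total_stride
        for name, dim in (("height", h), ("width", w)):
            if dim % s != 0 or dim < s:
                raise ValueError(
                    f"input {name} {dim} is not a positive multiple of the "
                    f"backbone stride {s}")


def build_backbone(profile: str, pretrained: bool = False,
                   weights_path: str | None = None,
                   extra_stem_pool: bool = True, seed: int = 0) -> ResNetBackbone:
    """Construct a backbone by profile name.

    ``pretrained=True`` requires an explicit ``weights_path`` to a saved
    ``.npz`` state dict; without one the call fails loudly rather than
    silently falling back to random initialisation.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown backbone profile {profile!r}; "
                         f"choose from {sorted(PROFILES)}")
    model = ResNetBackbone(PROFILES[profile], extra_stem_pool=extra_stem_pool,
                           seed=seed)
    if pretrained:
        if weights_path is None:
            raise RuntimeError(
                "pretrained=True requires weights_path: no pretrained weights "
                "can be downloaded here and random init will not be silently "
                "substituted")
        state = dict(np.load(weights_path))
        model.load_state_dict(state)
    return model


def extract_stages(model: ResNetBackbone, batch) -> StageFeatures:
    """Run the backbone on an image batch and return its four stage maps."""
    x = batch if isinstance(batch, Tensor) else Tensor(batch)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("image batch contains non-finite values")
    return model(x)
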