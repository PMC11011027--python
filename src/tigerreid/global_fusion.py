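"""Inverted feature-pyramid fusion (IFPM): the global branch.

Classic feature pyramids propagate deep semantics top-down into the
shallow, high-resolution levels.  Re-identification of striped animals
benefits from the opposite flow: shallow texture detail is pushed
bottom-up into the deepest, most semantic level.  Starting from the
shallowest stage map C1, each level is spatially down-sampled and
channel-expanded to the next stage's geometry, added to that stage map,
and passed through a 3x3 convolution with ReLU:

    P1 = ReLU(conv(proj(C1)  + C2))        # 512 x H/2 x W/2
    P2 = ReLU(conv(proj(P1)  + C3))        # 1024 x H/4 x W/4
    P3 = ReLU(conv(proj(P2)  + C4))        # 2048 x H/4 x W/4 (stride-1 level)

The deepest level P3 is then merged with C4 (elementwise sum by default,
keeping the channel count) and spatially average-pooled into the global
descriptor F_Global whose length equals the C4 channel width (2048 in the
full profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module

__all__ = [
    "PyramidFeatures",
    "DownsampleProject",
    "FuseLevel",
    "InvertedPyramid",
    "pool_global",
]


@dataclass
class PyramidFeatures:
    """Bottom-up fused maps plus the pooled global descriptor."""

    p1: Tensor
    p2: Tensor
    p3: Tensor
    f_global: Tensor          # (B, C4)
    fused_map: Tensor         # (B, C4, h4, w4): P3 + C4, input to the local branch


def _check_halving(in_hw: tuple[int, int], target_hw: tuple[int, int]) -> int:
    """Return the stride (1 or 2) implied by the spatial change, else raise."""
    if tuple(in_hw) == tuple(target_hw):
        return 1
    if in_hw[0] == 2 * target_hw[0] and in_hw[1] == 2 * target_hw[1]:
        return 2
    raise ValueError(
        f"pyramid level must keep or exactly halve the spatial size: "
        f"{tuple(in_hw)} -> {tuple(target_hw)} is neither")


class DownsampleProject(Module):
    """3x3 convolution (stride 1 or 2) + batch norm mapping one pyramid
    level's geometry onto the next stage's channels and spatial size."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng,
                 norm: str = "bn"):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.conv = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch) if norm == "bn" else None
        self.stride = stride

    def forward(self, x: Tensor, target_hw: tuple[int, int] | None = None) -> Tensor:
        if target_hw is not None:
            stride = _check_halving(x.shape[2:], target_hw)
            if stride != self.stride:
                raise ValueError(f"level was built with stride {self.stride} "
                                 f"but target size implies {stride}")
        out = self.conv(x)
        return self.bn(out) if self.bn is not None else out


class FuseLevel(Module):
    """Additive fusion: ReLU(conv3x3(P_prev + C_next)), channels preserved."""

    def __init__(self, channels: int, rng, norm: str = "bn"):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, padding=1, bias=False, rng=rng)
        self.bn = BatchNorm2d(channels) if norm == "bn" else None

    def forward(self, p_prev: Tensor, c_next: Tensor) -> Tensor:
        if p_prev.shape != c_next.shape:
            raise ValueError(f"fuse_level shape mismatch: {p_prev.shape} "
                             f"vs {c_next.shape}")
        out = self.conv(ag.add(p_prev, c_next))
        if self.bn is not None:
            out = self.bn(out)
        return ag.relu(out)


def pool_global(p3: Tensor, c4: Tensor, merge: str = "sum",
                reduce_conv: Conv2d | None = None) -> tuple[Tensor, Tensor]:
    """Merge the deepest pyramid level with C4 and average-pool it.

    Returns ``(f_global, fused_map)``; the un-pooled fused map is what the
    local branch consumes.  ``merge="sum"`` (default) preserves the C4
    channel count; ``merge="concat_reduce"`` concatenates and reduces back
    through a 1x1 convolution.
    """
    if p3.shape != c4.shape:
        raise ValueError(f"pool_global shape mismatch: {p3.shape} vs {c4.shape}")
    if merge == "sum":
        fused = ag.add(p3, c4)
    elif merge == "concat_reduce":
        if reduce_conv is None:
            raise ValueError("concat_reduce merge requires the reduction conv")
        fused = reduce_conv(ag.concat([p3, c4], axis=1))
    else:
        raise ValueError(f"unknown merge mode {merge!r}")
    return ag.global_avg_pool2d(fused), fused


class InvertedPyramid(Module):
    """Bottom-up fusion of the four backbone stages into F_Global."""

    def __init__(self, stage_widths: tuple[int, int, int, int],
                 merge: str = "sum", norm: str = "bn", seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = stage_widths
        # entry strides mirror the stage geometry: C2, C3 are half their
        # predecessor's size; C4 matches C3 (its down-sampling was removed)
        self.down1 = DownsampleProject(c1, c2, stride=2, rng=rng, norm=norm)
        self.down2 = DownsampleProject(c2, c3, stride=2, rng=rng, norm=norm)
        self.down3 = DownsampleProject(c3, c4, stride=1, rng=rng, norm=norm)
        self.fuse1 = FuseLevel(c2, rng, norm=norm)
        self.fuse2 = FuseLevel(c3, rng, norm=norm)
        self.fuse3 = FuseLevel(c4, rng, norm=norm)
        self.merge = merge
        self.reduce_conv = (Conv2d(2 * c4, c4, 1, bias=False, rng=rng)
                            if merge == "concat_reduce" else None)

    def forward(self, stages) -> PyramidFeatures:
        c1, c2, c3, c4 = stages.as_tuple()
        p1 = self.fuse1(self.down1(c1, target_hw=c2.shape[2:]), c2)
        p2 = self.fuse2(self.down2(p1, target_hw=c3.shape[2:]), c3)
        p3 = self.fuse3(self.down3(p2, target_hw=c4.shape[2:]), c4)
        f_global, fused = pool_global(p3, c4, merge=self.merge,
                                      reduce_conv=self.reduce_conv)
        return PyramidFeatures(p1, p2, p3, f_global, fused)

    # alias matching the operation's name in the docs
    build_pyramid = forward
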