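"""Local attention enhancement (LAEM): the part-based local branch.

The fused global map is cut into four equal horizontal blocks (left to
right along the body axis, so each block covers a contiguous quarter of
the animal).  Each block is max-pooled to 1x1, reduced to a quarter of
the input channel width by a 1x1 convolution, passed through dual-domain
(channel-then-spatial, CBAM-style) attention gating and a ReLU, and the
four enhanced part vectors L1..L4 are concatenated into F_Local — the
same length as the global descriptor.

By default the block is pooled to 1x1 *before* the attention, which makes
the spatial gate a single scalar; ``pool_position="post"`` instead runs
the attention on the full-resolution reduced block and pools afterwards.
All four blocks share one set of reduction/attention weights unless
``shared_weights=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Linear, Module

__all__ = [
    "LocalBlocks",
    "AttentionGates",
    "split_blocks",
    "BlockReduce",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "LocalBranch",
]


@dataclass
class LocalBlocks:
    """Intermediate and final products of the local branch."""

    blocks: list          # 4 maps, (B, C, h, w/4) each
    reduced: list         # 4 maps after pool + 1x1 conv, (B, C/4, ...)
    enhanced: list        # L1..L4 vectors, (B, C/4) each
    f_local: Tensor       # (B, C): concat of L1..L4


@dataclass
class AttentionGates:
    channel_gate: np.ndarray      # (B, C), strictly inside (0, 1)
    spatial_gate: np.ndarray      # (B, 1, h, w), strictly inside (0, 1)


def split_blocks(fused_map: Tensor, n_blocks: int = 4) -> list:
    """Cut a (B, C, H, W) map into ``n_blocks`` contiguous width slices."""
    w = fused_map.shape[3]
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if w % n_blocks != 0:
        raise ValueError(f"width {w} is not divisible into {n_blocks} blocks")
    bw = w // n_blocks
    return [ag.narrow(fused_map, 3, i * bw, bw) for i in range(n_blocks)]


class BlockReduce(Module):
    """Adaptive max-pool to 1x1 followed by a 1x1 channel-reducing conv."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv = Conv2d(in_ch, out_ch, 1, bias=True, rng=rng)

    def forward(self, block: Tensor) -> Tensor:
        if block.shape[1] != self.in_ch:
            raise ValueError(f"block has {block.shape[1]} channels, "
                             f"reduction expects {self.in_ch}")
        pooled = ag.global_max_pool2d(block)                 # (B, C)
        pooled = ag.reshape(pooled, (*pooled.shape, 1, 1))   # (B, C, 1, 1)
        return self.conv(pooled)                             # (B, C/4, 1, 1)

    def reduce_only(self, block: Tensor) -> Tensor:
        """1x1 conv without pooling (the pool-after-attention variant)."""
        if block.shape[1] != self.in_ch:
            raise ValueError(f"block has {block.shape[1]} channels, "
                             f"reduction expects {self.in_ch}")
        return self.conv(block)


class ChannelAttention(Module):
    """Squeeze both spatial poolings through a shared bottleneck MLP.

    gate = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F))), one value per channel.
    """

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if channels < reduction or channels % reduction != 0:
            raise ValueError(f"channel count {channels} must be a multiple of "
                             f"the reduction ratio {reduction}")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = Linear(hidden, channels, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = self.fc2(ag.relu(self.fc1(ag.global_avg_pool2d(x))))
        mx = self.fc2(ag.relu(self.fc1(ag.global_max_pool2d(x))))
        return ag.sigmoid(ag.add(avg, mx))                   # (B, C)


class SpatialAttention(Module):
    """Gate every position through a k x k conv over the channel-wise
    mean and max maps."""

    def __init__(self, kernel: int = 7, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if kernel % 2 != 1:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel}")
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(self.conv(ag.channel_mean_max(x)))  # (B, 1, h, w)


class CBAM(Module):
    """Sequential channel-then-spatial multiplicative gating.

    Both gates are sigmoid outputs, so the module can only attenuate:
    |CBAM(F)| <= |F| elementwise.
    """

    def __init__(self, channels: int, reduction: int = 16, kernel: int = 7,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cg = self.channel(x)
        xc = ag.mul(x, ag.reshape(cg, (*cg.shape, 1, 1)))
        sg = self.spatial(xc)
        return ag.mul(xc, sg)

    def gates(self, x: Tensor) -> AttentionGates:
        """Evaluate both gates for inspection (spatial gate on the
        channel-gated map, as applied in forward)."""
        cg = self.channel(x)
        xc = ag.mul(x, ag.reshape(cg, (*cg.shape, 1, 1)))
        sg = self.spatial(xc)
        return AttentionGates(cg.data, sg.data)


class LocalBranch(Module):
    """Split -> reduce -> dual-domain attention -> ReLU -> concatenate."""

    def __init__(self, in_ch: int, n_blocks: int = 4, reduction: int = 16,
                 kernel: int = 7, shared_weights: bool = True,
                 pool_position: str = "pre", seed: int = 0):
        super().__init__()
        if in_ch % n_blocks != 0:
            raise ValueError(f"channel width {in_ch} not divisible by "
                             f"{n_blocks} blocks")
        if pool_position not in ("pre", "post"):
            raise ValueError(f"pool_position must be 'pre' or 'post', "
                             f"got {pool_position!r}")
        rng = np.random.default_rng(seed)
        self.n_blocks = n_blocks
        self.local_dim = in_ch // n_blocks
        self.pool_position = pool_position
        self.shared_weights = shared_weights
        n_units = 1 if shared_weights else n_blocks
        for i in range(n_units):
            setattr(self, f"reduce{i}", BlockReduce(in_ch, self.local_dim, rng))
            setattr(self, f"cbam{i}", CBAM(self.local_dim, reduction, kernel,
                                           rng=rng))

    def _unit(self, i: int) -> tuple[BlockReduce, CBAM]:
        j = 0 if self.shared_weights else i
        return getattr(self, f"reduce{j}"), getattr(self, f"cbam{j}")

    def forward(self, fused_map: Tensor) -> LocalBlocks:
        blocks = split_blocks(fused_map, self.n_blocks)
        reduced, enhanced = [], []
        for i, block in enumerate(blocks):
            red_mod, cbam = self._unit(i)
            if self.pool_position == "pre":
                red = red_mod(block)                       # (B, C/4, 1, 1)
                out = ag.relu(cbam(red))
                vec = ag.flatten(out)
            else:
                red = red_mod.reduce_only(block)           # (B, C/4, h, w/4)
                out = ag.relu(cbam(red))
                vec = ag.global_max_pool2d(out)
            reduced.append(red)
            enhanced.append(vec)
        f_local = ag.concat(enhanced, axis=1)
        return LocalBlocks(blocks, reduced, enhanced, f_local)
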