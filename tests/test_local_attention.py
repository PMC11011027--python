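"""Local branch: block split, reduction, dual-domain attention gates."""

import numpy as np
import pytest

from tigerreid import (CBAM, ChannelAttention, LocalBranch, SpatialAttention,
                       Tensor, split_blocks)
from tigerreid.local_attention import BlockReduce
from tigerreid import autograd as ag

from conftest import zero_weights


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def test_split_partition_is_exact(rng):
    """Width-concat of the blocks reconstructs the input bit for bit."""
    x = Tensor(rng.normal(size=(2, 8, 4, 16)).astype(np.float32))
    blocks = split_blocks(x, 4)
    assert [b.shape for b in blocks] == [(2, 8, 4, 4)] * 4
    np.testing.assert_array_equal(ag.concat(blocks, axis=3).data, x.data)


def test_split_single_block_is_identity(rng):
    x = Tensor(rng.normal(size=(1, 4, 2, 6)))
    (b,) = split_blocks(x, 1)
    np.testing.assert_array_equal(b.data, x.data)


def test_split_indivisible_width_rejected():
    with pytest.raises(ValueError, match="divisible"):
        split_blocks(Tensor(np.zeros((1, 8, 8, 15))), 4)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def test_reduce_block_pools_per_channel_max(rng):
    """Pooled vector equals an explicit per-channel max loop."""
    red = BlockReduce(16, 4, rng=np.random.default_rng(0))
    block = Tensor(rng.normal(size=(2, 16, 2, 2)))
    pooled = ag.global_max_pool2d(block)
    for b in range(2):
        for c in range(16):
            m = -np.inf
            for i in range(2):
                for j in range(2):
                    m = max(m, block.data[b, c, i, j])
            assert pooled.data[b, c] == pytest.approx(m)
    out = red(block)
    assert out.shape == (2, 4, 1, 1)


def test_reduce_block_wrong_channels_rejected():
    red = BlockReduce(16, 4, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="channels"):
        red(Tensor(np.zeros((1, 8, 2, 2))))


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

def test_channel_gate_is_half_with_zero_weights(rng):
    att = ChannelAttention(16, reduction=4, rng=np.random.default_rng(0))
    zero_weights(att)
    gate = att(Tensor(rng.normal(size=(2, 16, 3, 3))))
    np.testing.assert_allclose(gate.data, 0.5, atol=1e-7)


def test_channel_gate_strictly_in_unit_interval(rng):
    att = ChannelAttention(32, reduction=8, rng=np.random.default_rng(1))
    gate = att(Tensor(rng.normal(size=(3, 32, 4, 4)) * 5))
    assert np.all(gate.data > 0) and np.all(gate.data < 1)


def test_channel_gate_matches_hand_computation(rng):
    """Pinned tiny weights on a 4-channel 2x2 input, evaluated by hand."""
    att = ChannelAttention(4, reduction=2, rng=np.random.default_rng(2))
    w1 = np.arange(8, dtype=np.float32).reshape(2, 4) * 0.1
    w2 = np.arange(8, dtype=np.float32).reshape(4, 2) * 0.05
    att.fc1.weight.data[...] = w1
    att.fc2.weight.data[...] = w2
    x = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
    avg = x.mean(axis=(2, 3))
    mx = x.max(axis=(2, 3))
    mlp = lambda v: np.maximum(v @ w1.T, 0) @ w2.T
    expected = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
    gate = att(Tensor(x))
    np.testing.assert_allclose(gate.data, expected, rtol=1e-5)


def test_channel_attention_rejects_indivisible_reduction():
    with pytest.raises(ValueError, match="reduction"):
        ChannelAttention(8, reduction=16)


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------

def test_spatial_gate_uniform_with_zero_weights(rng):
    att = SpatialAttention(kernel=7, rng=np.random.default_rng(0))
    zero_weights(att)
    gate = att(Tensor(rng.normal(size=(2, 8, 4, 4))))
    assert gate.shape == (2, 1, 4, 4)
    np.testing.assert_allclose(gate.data, 0.5, atol=1e-7)


def test_spatial_gate_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        SpatialAttention(kernel=4)


def test_spatial_gate_degenerate_1x1_input(rng):
    att = SpatialAttention(kernel=7, rng=np.random.default_rng(3))
    gate = att(Tensor(rng.normal(size=(2, 8, 1, 1))))
    assert gate.shape == (2, 1, 1, 1)
    assert np.all((gate.data > 0) & (gate.data < 1))


def test_spatial_gate_matches_hand_computation(rng):
    """1x1-kernel weights pinned: gate = sigmoid(w0*mean + w1*max + b)."""
    att = SpatialAttention(kernel=1, rng=np.random.default_rng(4))
    att.conv.weight.data[...] = np.array([0.7, -0.4]).reshape(1, 2, 1, 1)
    att.conv.bias.data[...] = 0.2
    x = rng.normal(size=(1, 5, 3, 3)).astype(np.float32)
    expected = 1 / (1 + np.exp(-(0.7 * x.mean(axis=1) - 0.4 * x.max(axis=1) + 0.2)))
    gate = att(Tensor(x))
    np.testing.assert_allclose(gate.data[:, 0], expected, rtol=1e-5)


# ---------------------------------------------------------------------------
# CBAM composition
# ---------------------------------------------------------------------------

def test_cbam_zero_weights_quarter_scaling(rng):
    """Both gates collapse to 0.5, so the output is exactly 0.25 x input."""
    cbam = CBAM(16, reduction=4, rng=np.random.default_rng(0))
    zero_weights(cbam)
    x = rng.normal(size=(2, 16, 3, 3)).astype(np.float32)
    out = cbam(Tensor(x))
    np.testing.assert_allclose(out.data, 0.25 * x, rtol=1e-5, atol=1e-7)


def test_cbam_never_amplifies(rng):
    cbam = CBAM(16, reduction=4, rng=np.random.default_rng(5))
    x = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
    out = cbam(Tensor(x))
    assert np.all(np.abs(out.data) <= np.abs(x) + 1e-7)


def test_cbam_matches_composed_gate_oracle(rng):
    """Channel gate applied first, spatial gate on the gated map."""
    cbam = CBAM(4, reduction=2, kernel=1, rng=np.random.default_rng(6))
    x = Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32))
    cg = cbam.channel(x).data
    xc = x.data * cg[:, :, None, None]
    sg = cbam.spatial(Tensor(xc)).data
    expected = xc * sg
    np.testing.assert_allclose(cbam(x).data, expected, rtol=1e-5)
    gates = cbam.gates(x)
    np.testing.assert_allclose(gates.channel_gate, cg, rtol=1e-6)
    np.testing.assert_allclose(gates.spatial_gate, sg, rtol=1e-6)


# ---------------------------------------------------------------------------
# full branch
# ---------------------------------------------------------------------------

def test_local_branch_output_length(rng):
    branch = LocalBranch(256, seed=0)
    out = branch(Tensor(rng.normal(size=(2, 256, 2, 4))))
    assert len(out.blocks) == 4
    assert out.f_local.shape == (2, 256)
    assert all(v.shape == (2, 64) for v in out.enhanced)
    assert out.f_local.data.min() >= 0.0, "part vectors are post-ReLU"
    np.testing.assert_array_equal(
        out.f_local.data, np.concatenate([v.data for v in out.enhanced], axis=1))


def test_local_branch_zero_input_zero_output():
    branch = LocalBranch(64, reduction=16, seed=1)
    out = branch(Tensor(np.zeros((1, 64, 2, 4))))
    np.testing.assert_allclose(out.f_local.data, 0.0, atol=1e-7)


def test_local_branch_locality_and_shared_weights(rng):
    """Swapping the two middle blocks swaps L2/L3 and leaves L1/L4 alone."""
    branch = LocalBranch(64, reduction=16, seed=2)
    x = rng.normal(size=(1, 64, 2, 8)).astype(np.float32)
    swapped = x.copy()
    swapped[..., 2:4], swapped[..., 4:6] = x[..., 4:6], x[..., 2:4]
    a = branch(Tensor(x))
    b = branch(Tensor(swapped))
    np.testing.assert_allclose(b.enhanced[1].data, a.enhanced[2].data, rtol=1e-5)
    np.testing.assert_allclose(b.enhanced[2].data, a.enhanced[1].data, rtol=1e-5)
    np.testing.assert_array_equal(b.enhanced[0].data, a.enhanced[0].data)
    np.testing.assert_array_equal(b.enhanced[3].data, a.enhanced[3].data)


def test_local_branch_pool_after_attention_variant(rng):
    branch = LocalBranch(64, reduction=16, pool_position="post", seed=3)
    out = branch(Tensor(rng.normal(size=(1, 64, 2, 8))))
    assert out.f_local.shape == (1, 64)
    assert out.reduced[0].shape == (1, 16, 2, 2), \
        "post-pool variant keeps spatial structure through the attention"


def test_local_branch_unshared_weights_differ(rng):
    shared = LocalBranch(64, seed=4)
    unshared = LocalBranch(64, shared_weights=False, seed=4)
    x = Tensor(np.tile(rng.normal(size=(1, 64, 2, 2)).astype(np.float32), (1, 1, 1, 4)))
    a = shared(x)
    b = unshared(x)
    # identical block contents -> identical part vectors only when shared
    np.testing.assert_allclose(a.enhanced[0].data, a.enhanced[1].data, rtol=1e-5)
    assert not np.allclose(b.enhanced[0].data, b.enhanced[1].data)
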