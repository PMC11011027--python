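"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains convolutional descriptor networks on CPU; this module
supplies exactly the tensor operations those networks need (convolution,
batch normalisation, pooling, affine maps, elementwise nonlinearities,
concatenation/slicing and fused softmax cross-entropy), each with an
analytic backward pass.  Gradients are accumulated by reverse topological
sweep over the recorded operation graph.

Everything is float32 end to end.  Correctness of every backward pass is
pinned by central-difference gradient checks in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "batch_norm2d",
    "max_pool2d",
    "global_avg_pool2d",
    "global_max_pool2d",
    "concat",
    "narrow",
    "reshape",
    "flatten",
    "linear",
    "softmax",
    "softmax_cross_entropy",
    "numerical_gradient",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / descriptor extraction)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_pending")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autodiff ------------------------------------------------------------
    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run the reverse sweep from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter / input
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._backward(g)
                for p, pg in node._consume_parent_grads():
                    key = id(p)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # The backward closures stash per-parent grads here to keep the sweep
    # allocation-light.
    def _consume_parent_grads(self):
        out = self._pending  # type: ignore[attr-defined]
        del self._pending  # type: ignore[attr-defined]
        return out


# ---------------------------------------------------------------------------
# graph construction helpers
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list[tuple[Tensor, np.ndarray]]] | None) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req and backward is not None:
        live = tuple(p for p in parents if p.requires_grad or p._backward is not None)
        out._parents = live

        def run(g: np.ndarray, _out=out, _bw=backward):
            _out._pending = [(p, pg) for p, pg in _bw(g) if pg is not None
                             and (p.requires_grad or p._backward is not None)]

        out._backward = run
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(g):
        return [(a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape))]

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(g):
        return [(a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape))]

    return _make(data, (a, b), bw)


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        return [(a, g * np.float32(s))]

    return _make(a.data * np.float32(s), (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def bw(g):
        return [(a, g @ b.data.T), (b, a.data.T @ g)]

    return _make(data, (a, b), bw)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x @ weight.T + bias  with x of shape (B, in), weight (out, in)."""
    data = x.data @ weight.data.T
    if bias is not None:
        data = data + bias.data

    def bw(g):
        grads = [(x, g @ weight.data), (weight, g.T @ x.data)]
        if bias is not None:
            grads.append((bias, g.sum(axis=0)))
        return grads

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, bw)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0).astype(np.float32)

    def bw(g):
        return [(x, g * mask)]

    return _make(data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    x = _as_tensor(x)
    s = expit(x.data.astype(np.float64)).astype(np.float32)

    def bw(g):
        return [(x, g * s * (1.0 - s))]

    return _make(s, (x,), bw)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = x.data.shape

    def bw(g):
        return [(x, g.reshape(old))]

    return _make(x.data.reshape(shape), (x,), bw)


def flatten(x: Tensor) -> Tensor:
    return reshape(x, (x.data.shape[0], -1))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        return list(zip(tensors, pieces))

    return _make(data, tuple(tensors), bw)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (used for the horizontal block split)."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def bw(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        return [(x, full)]

    return _make(x.data[idx], (x,), bw)


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(B,C,Hp,Wp) -> columns (B*OH*OW, C*kh*kw) plus output spatial dims."""
    b, c, hp, wp = xp.shape
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                      # B,C,OH,OW,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; weight (OC, C, kh, kw), x (B, C, H, W)."""
    b, c, h, w = x.data.shape
    oc, wc, kh, kw = weight.data.shape
    if wc != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {wc}")
    sh = sw = int(stride)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols, oh, ow = _im2col(xp, kh, kw, sh, sw)
    wmat = weight.data.reshape(oc, -1)
    out = cols @ wmat.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(b, oh, ow, oc).transpose(0, 3, 1, 2)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(b * oh * ow, oc)
        gw = (g2.T @ cols).reshape(weight.data.shape)
        gcols = (g2 @ wmat).reshape(b, oh, ow, c, kh, kw)
        gxp = np.zeros_like(xp)
        # for a fixed kernel offset the strided target slices never overlap
        gc = gcols.transpose(0, 3, 1, 2, 4, 5)       # B,C,OH,OW,kh,kw
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += gc[:, :, :, :, i, j]
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g2.sum(axis=0)))
        return grads

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    b, c, h, w = x.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    hp, wp = xp.shape[2:]
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(b, c, oh, ow, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        ki, kj = np.divmod(arg, kernel)
        oi = np.arange(oh)[None, None, :, None] * stride
        oj = np.arange(ow)[None, None, None, :] * stride
        ri = (oi + ki).ravel()
        rj = (oj + kj).ravel()
        bi = np.repeat(np.arange(b), c * oh * ow)
        ci = np.tile(np.repeat(np.arange(c), oh * ow), b)
        gxp = np.zeros_like(xp)
        np.add.at(gxp, (bi, ci, ri, rj), g.ravel())
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        return [(x, gx.astype(np.float32))]

    return _make(out.astype(np.float32), (x,), bw)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C): spatial mean."""
    b, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def bw(g):
        gx = np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape)
        return [(x, np.ascontiguousarray(gx))]

    return _make(data, (x,), bw)


def global_max_pool2d(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C): per-channel spatial max (adaptive max-pool to 1x1)."""
    b, c, h, w = x.data.shape
    flat = x.data.reshape(b, c, h * w)
    arg = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        return [(x, gflat.reshape(x.data.shape))]

    return _make(data, (x,), bw)


def channel_mean_max(x: Tensor) -> Tensor:
    """Concatenate channel-wise mean and max maps -> (B,2,H,W)."""
    b, c, h, w = x.data.shape
    mean = x.data.mean(axis=1, keepdims=True)
    arg = x.data.argmax(axis=1, keepdims=True)
    mx = np.take_along_axis(x.data, arg, axis=1)
    data = np.concatenate([mean, mx], axis=1)

    def bw(g):
        gmean = np.broadcast_to(g[:, :1] / c, x.data.shape).copy()
        gmax = np.zeros_like(x.data)
        np.put_along_axis(gmax, arg, g[:, 1:2], axis=1)
        return [(x, gmean + gmax)]

    return _make(data, (x,), bw)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation on (B,C,H,W).

    Running statistics are updated in place when `training` is true; the
    eval path is a pure affine map through the stored statistics.
    """
    b, c, h, w = x.data.shape
    if training:
        n = b * h * w
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        unbiased = var * (n / max(n - 1, 1))
        running_var *= (1 - momentum)
        running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            n = b * h * w
            s1 = gxhat.sum(axis=(0, 2, 3))
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3))
            gx = (inv[None, :, None, None] / n) * (
                n * gxhat - s1[None, :, None, None] - xhat * s2[None, :, None, None])
        else:
            gx = gxhat * inv[None, :, None, None]
        return [(x, gx.astype(np.float32)), (gamma, ggamma), (beta, gbeta)]

    return _make(data.astype(np.float32), (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch, fused with the softmax."""
    labels = np.asarray(labels)
    b = logits.data.shape[0]
    p = softmax(logits.data.astype(np.float64), axis=1)
    eps = 1e-12
    loss = -np.log(np.clip(p[np.arange(b), labels], eps, None)).mean()

    def bw(g):
        gl = p.copy()
        gl[np.arange(b), labels] -= 1.0
        return [(logits, (g * gl / b).astype(np.float32))]

    return _make(np.float32(loss), (logits,), bw)


# ---------------------------------------------------------------------------
# verification helper
# ---------------------------------------------------------------------------

def numerical_gradient(f: Callable[[], Tensor], param: Tensor,
                       eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. every entry of param."""
    grad = np.zeros_like(param.data, dtype=np.float64)
    flat = param.data.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(f().data)
        flat[i] = orig - eps
        lo = float(f().data)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad
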