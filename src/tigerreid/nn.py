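"""Layer and optimiser primitives built on :mod:`tigerreid.autograd`.

Follows the familiar module/parameter idiom: a :class:`Module` owns named
:class:`~tigerreid.autograd.Tensor` parameters and child modules, exposes
``train()``/``eval()`` modes and a flat ``state_dict``.  Only the layers the
re-identification network needs are provided.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sequential",
    "SGD",
]


class Module:
    """Base class: parameter registry, mode flag, state-dict (de)serialisation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # attribute magic keeps layer definitions terse
    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for mname, m in self._modules.items():
            out.update(m.state_dict(prefix + mname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            src = np.asarray(state[prefix + k], dtype=np.float32)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data[...] = src
        for k in self._buffers:
            self._buffers[k][...] = np.asarray(state[prefix + k])
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """He-normal initialised 2-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta,
                               self.running_mean, self.running_var,
                               training=self.training,
                               momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 std: float | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features) if std is None else std
        self.weight = Tensor(rng.normal(0.0, std, (out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with momentum, weight decay and
    per-group learning rates (classifier vs. everything else)."""

    def __init__(self, param_groups: list[dict], momentum: float = 0.0,
                 weight_decay: float = 0.0):
        # each group: {"params": [Tensor...], "lr": float}
        self.param_groups = param_groups
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [[np.zeros_like(p.data) for p in g["params"]]
                          for g in param_groups]

    def zero_grad(self) -> None:
        for g in self.param_groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for group, vel in zip(self.param_groups, self._velocity):
            lr = group["lr"]
            for p, v in zip(group["params"], vel):
                if p.grad is None:
                    continue
                g = p.grad + self.weight_decay * p.data
                v *= self.momentum
                v += g
                p.data -= lr * v
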