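"""Neural-network layer library on top of :mod:`dcclnet.autodiff`.

Provides the building blocks the segmentation backbones need — 2D
convolution, linear projections, batch/layer normalisation — plus a
module container with named parameters/buffers, state-dict
(de)serialisation and an SGD optimizer with momentum.

Initialisation draws from an explicit ``numpy.random.Generator`` so that
model construction is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Container with named parameters, buffers and submodules."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state dict ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out["buffer:" + name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = []
        for name, p in params.items():
            if name not in state:
                missing.append(name)
                continue
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {name}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()
        if missing:
            raise ValueError(f"state dict missing parameters: {missing}")
        self._load_buffers(state, "")

    def _load_buffers(self, state: dict[str, np.ndarray], prefix: str) -> None:
        for name in list(self._buffers):
            key = "buffer:" + prefix + name
            if key in state:
                self._set_buffer(name, state[key])
        for mname, m in self._modules.items():
            m._load_buffers(state, prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Conv2d(Module):
    """3x3-style stride-1 convolution with zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred ** 2).mean(axis=(0, 2, 3), keepdims=True)
            if ad.is_grad_enabled():
                m = self.momentum
                self._set_buffer("running_mean",
                                 (1 - m) * self.running_mean + m * mu.data.reshape(-1))
                self._set_buffer("running_var",
                                 (1 - m) * self.running_var + m * var.data.reshape(-1))
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var[None, :, None, None] + self.eps)
            xhat = (x - mu) * inv
        g = ad.reshape(self.gamma, (1, -1, 1, 1))
        b = ad.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class LayerNorm(Module):
    """Normalisation over the last axis (token embedding dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        xhat = centred * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        if len({id(p) for p in self.params}) != len(self.params):
            raise ValueError("duplicate parameters passed to SGD")
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"lr": self.lr, "velocity": [v.copy() for v in self._velocity]}

    def load_state_dict(self, state: dict) -> None:
        self.lr = state["lr"]
        self._velocity = [np.asarray(v, dtype=DTYPE).copy() for v in state["velocity"]]
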