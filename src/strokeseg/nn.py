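"""Neural-network building blocks over the :mod:`strokeseg.autograd` engine.

Mirrors the familiar Module / Parameter idiom: modules own parameters and
submodules, expose ``parameters()`` / ``state_dict()`` and a train/eval
switch (which controls batch-norm statistics).  Weight initialisation
draws from an explicit :class:`numpy.random.Generator` passed to each
constructor, so building a model twice from the same seed yields
bit-identical parameters.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import (Tensor, conv2d, interp2d, bilinear_matrix, matmul,
                       maxpool2d, relu, sigmoid)

_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-scanned parameter/submodule registry."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield from m.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, ModuleList):
                for m in val:
                    yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialisation -------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val._named_buffers(f"{full}.")
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield from m._named_buffers(f"{full}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield full, val

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(_DTYPE).copy()
        for name, buf in buffers.items():
            buf[...] = state[name]


class ModuleList(list):
    """Plain list of modules, recognised by the registry scan."""


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=_DTYPE)
        self.running_var = np.ones(ch, dtype=_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / C
            with np.errstate(all="ignore"):
                self.running_mean += self.momentum * (
                    mu.data.reshape(-1) - self.running_mean)
                unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
                self.running_var += self.momentum * (unbiased - self.running_var)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, C, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        return xhat * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    """Bilinear resampling to a fixed output size (separable matrices)."""

    _cache: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = tuple(out_hw)

    @classmethod
    def _matrix(cls, n_out: int, n_in: int) -> np.ndarray:
        key = (n_out, n_in)
        if key not in cls._cache:
            cls._cache[key] = bilinear_matrix(n_out, n_in)
        return cls._cache[key]

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        ho, wo = self.out_hw
        if (ho, wo) == (H, W):
            return x
        return interp2d(x, self._matrix(ho, H), self._matrix(wo, W))


def upsample_to(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    return Upsample(out_hw)(x)
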