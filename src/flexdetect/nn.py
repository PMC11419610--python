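"""Layers and an optimizer built on :mod:`flexdetect.autograd`.

Provides the building blocks shared by the deformable, fusion and demo-model
modules: plain convolution, batch normalization, the CBL composite block
(convolution -> batch norm -> SiLU), a 2x2 stride-2 transposed convolution,
stride-1 max pooling, and Adam.

Layers expose ``linear_mode``-style switches where the fusion blocks need to
be provably linear for superposition tests: constructing a block with
``norm=False, activation="identity"`` removes every nonlinearity.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .autograd import Tensor, concat, conv2d, maximum

__all__ = [
    "Parameter", "Module", "Conv2d", "BatchNorm2d", "CBL",
    "ConvTranspose2x2", "max_pool2d_s1", "Adam", "Sequential",
]


class Parameter(Tensor):
    """Trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=float), requires_grad=True)


class Module:
    """Minimal layer base: parameter discovery, train/eval mode, n_params."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _extract_params(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            for m in _extract_modules(value):
                m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- serialization: flat named-tensor archive ---------------------------
    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                out.append((prefix + name, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix + name + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v.named_parameters(f"{prefix}{name}.{i}."))
                    elif isinstance(v, Parameter):
                        out.append((f"{prefix}{name}.{i}", v))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=float).reshape(p.data.shape)


def _extract_params(value) -> Iterable[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _extract_params(v)


def _extract_modules(value) -> Iterable["Module"]:
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _extract_modules(v)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


_ACTS = {
    "silu": lambda t: t.silu(),
    "sigmoid": lambda t: t.sigmoid(),
    "identity": lambda t: t,
    "relu": lambda t: maximum(t, 0.0),
}


class CBL(Module):
    """Convolution -> batch normalization -> SiLU composite block."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 norm: bool = True, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, bias=not norm, rng=rng)
        self.bn = BatchNorm2d(out_ch) if norm else None
        self.act = activation

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return _ACTS[self.act](y)


class ConvTranspose2x2(Module):
    """2x2, stride-2 transposed convolution (exact 2x spatial upsampling).

    Implemented as a 1x1 projection to ``out_ch * 4`` followed by
    depth-to-space, which is algebraically identical to the transposed
    convolution and needs no new autodiff primitive.
    """

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.out_ch = out_ch
        self.weight = Parameter(_kaiming(rng, (out_ch * 4, in_ch, 1, 1), in_ch))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        y = conv2d(x, self.weight, None, stride=1, pad=0)  # (n, out*4, h, w)
        y = y.reshape(n, self.out_ch, 2, 2, h, w)
        y = y.transpose(0, 1, 4, 2, 5, 3)  # n, c, h, 2, w, 2
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1, 1)
        return y

    def n_params(self) -> int:  # matches a true 2x2 transposed conv
        return super().n_params()


def max_pool2d_s1(x: Tensor, k: int = 5) -> Tensor:
    """k x k max pooling, stride 1, same-size output (SPPF-style)."""
    pad = k // 2
    xp = x.pad2d(pad, value=-1e30)
    h, w = x.shape[-2], x.shape[-1]
    out = None
    for dy in range(k):
        for dx in range(k):
            window = xp[..., dy:dy + h, dx:dx + w]
            out = window if out is None else maximum(out, window)
    return out


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer over :class:`Parameter` lists."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
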