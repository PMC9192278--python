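"""Layer and optimizer primitives on top of the autodiff engine.

Conventions follow the usual NCHW deep-learning layout.  Normalization is
per-sample (statistics over each image's own spatial extent), so inference
is deterministic and independent of batch composition.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "SeparableConv2d", "ChannelNorm", "ReLU",
           "Sigmoid", "Sequential", "SEGate", "Adam"]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack: list = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__.values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 2D convolution with He-initialized weights."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 pad: str = "same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.pad = pad
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, pad=self.pad)


class SeparableConv2d(Module):
    """Depthwise spatial filter followed by a 1x1 pointwise mix — the
    factorization whose multiply count is (1/N + 1/k^2) of a full conv."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 pad: str = "same", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.depthwise = Tensor(rng.standard_normal((in_ch, kernel, kernel)) * scale,
                                requires_grad=True)
        self.pointwise = Conv2d(in_ch, out_ch, kernel=1, rng=rng)
        self.pad = pad

    def forward(self, x):
        return self.pointwise(ad.depthwise_conv2d(x, self.depthwise, pad=self.pad))


class ChannelNorm(Module):
    """Per-sample, per-channel normalization over (H, W) with a learned
    affine rescaling — keeps activations well-scaled during training while
    leaving single-image inference deterministic."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = ad.tmean(x, axis=(2, 3), keepdims=True)
        xc = x - mu
        var = ad.tmean(xc * xc, axis=(2, 3), keepdims=True)
        xhat = xc / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class SEGate(Module):
    """Squeeze-excitation channel attention.

    Global average pool -> bottleneck of width C/r -> ReLU -> expand back
    to C -> logistic gate in (0, 1) -> multiply each channel by its gate.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        rng = rng or np.random.default_rng(0)
        self.squeeze = Conv2d(channels, channels // reduction, kernel=1, rng=rng)
        self.expand = Conv2d(channels // reduction, channels, kernel=1, rng=rng)
        self.channels, self.reduction = channels, reduction

    def gates(self, x) -> Tensor:
        s = ad.global_avg_pool(x)
        s = ad.relu(self.squeeze(s))
        return ad.sigmoid(self.expand(s))

    def forward(self, x):
        return x * self.gates(x)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
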