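"""Trainable layers: convolutions, normalization, dropout.

He-normal initialization throughout (the networks use rectifier-family
activations). Layers are deliberately minimal — just what the U-Net
generators and patch discriminators require.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from .functional import conv_nd

__all__ = ["Module", "Conv", "ConvTranspose2x", "BatchNorm", "SpatialDropout"]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def astype(self, dtype):
        """Cast all parameters (float32 trades precision for speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = m.running_mean.astype(dtype)
                m.running_var = m.running_var.astype(dtype)
        return self

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv(Module):
    """n-D convolution (dim inferred from kernel tuple length)."""

    def __init__(self, cin: int, cout: int, kernel, *, dim: int, stride=1,
                 pad="same", rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        kernel = tuple(kernel) if isinstance(kernel, (tuple, list)) else (kernel,) * dim
        fan_in = cin * int(np.prod(kernel))
        self.weight = Tensor(he_normal(rng, (cout, cin) + kernel, fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2x(Module):
    """2x transposed convolution: zero-insertion upsampling then a stride-1 conv.

    Equivalent to a fractionally strided convolution; doubles every spatial
    axis. Counts as a single convolutional layer.
    """

    def __init__(self, cin: int, cout: int, kernel=3, *, dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.dim = dim
        self.conv = Conv(cin, cout, kernel, dim=dim, stride=1, pad="same", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        d = self.dim
        up = x.dilate((2,) * d)
        # dilation yields size 2n-1; pad one trailing zero per axis to reach 2n
        pw = [(0, 0), (0, 0)] + [(0, 1)] * d
        return self.conv(up.pad(pw))


class BatchNorm(Module):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        d = x.ndim - 2
        axes = (0,) + tuple(range(2, 2 + d))
        cshape = (1, -1) + (1,) * d
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(cshape).astype(x.data.dtype))
            var = Tensor(self.running_var.reshape(cshape).astype(x.data.dtype))
            xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma.reshape(cshape) + self.beta.reshape(cshape)


class SpatialDropout(Module):
    """Drops whole feature maps with probability `rate` (training mode only)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        d = x.ndim - 2
        keep = self.rng.random((x.shape[0], x.shape[1]) + (1,) * d) >= self.rate
        mask = keep.astype(x.data.dtype) / (1.0 - self.rate)
        return x * Tensor(mask)
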