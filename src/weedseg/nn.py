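"""Neural-network building blocks over the :mod:`weedseg.autodiff` engine.

Modules hold :class:`~weedseg.autodiff.Tensor` parameters and recurse through
attributes for parameter collection and (de)serialization, mirroring the
familiar ``Module``/``state_dict`` idiom.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "ModuleList", "Sequential",
    "Conv2d", "DepthwiseConv2d", "Linear", "LayerNorm", "GRN",
    "ReLU", "GELU", "Sigmoid", "Identity",
]


class Module:
    """Base class: attribute-recursive parameter registry."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, arr in state.items():
            p = own[name]
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=p.data.dtype).copy()


class ModuleList(Module, list):
    def __init__(self, modules=()):
        list.__init__(self, modules)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self):
            yield from m.named_parameters(f"{prefix}{i}.")


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(np.asarray(arr, dtype=np.float32), requires_grad=True)


class Conv2d(Module):
    """2-D convolution; He-normal init unless ``init_std`` is given."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, init_std: float | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        std = init_std if init_std is not None else np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = _param(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = _param(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, padding: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * kernel))
        self.weight = _param(rng.normal(0.0, std, (channels, kernel, kernel)))
        self.bias = _param(np.zeros(channels))
        self.padding = padding

    def forward(self, x):
        return ad.depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.weight = _param(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = _param(np.zeros(out_f)) if bias else None

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, channels: int, axis: int = 1, eps: float = 1e-6):
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.axis = axis
        self.eps = eps

    def forward(self, x):
        return ad.layer_norm(x, self.gamma, self.beta, axis=self.axis, eps=self.eps)


class GRN(Module):
    """Global response normalization over spatial dims of an NCHW tensor."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.gamma = _param(np.zeros(channels))
        self.beta = _param(np.zeros(channels))
        self.eps = eps

    def forward(self, x):
        c = x.shape[1]
        g2 = (x * x).sum(axis=(2, 3), keepdims=True)          # (n, c, 1, 1)
        gx = (g2 + 1e-12) ** 0.5
        nx = gx / (gx.mean(axis=1, keepdims=True) + self.eps)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return gamma * (x * nx) + beta + x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x
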