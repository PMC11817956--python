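"""Layers and module containers over the autodiff tensor engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # even inside no_grad scaffolding


class Module:
    """Container with recursive parameter discovery and state dicts."""

    def modules(self):
        def walk(name, value):
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            if not name.startswith("_"):
                yield from walk(name, value)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, mod in self.modules():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict, strict: bool = True):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if strict and missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, arr in state.items():
            if name not in own:
                if strict:
                    raise KeyError(f"unexpected parameter: {name}")
                continue
            p = own[name]
            if p.data.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=np.float32).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride=1,
                 padding=None, bias: bool = True, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv3d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class ConvTranspose3d(Module):
    """Kernel-2 / stride-2 learnable upsampling."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 2,
                 bias: bool = True, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, stride, stride, stride),
                                         in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=np.float32))

    def forward(self, x):
        axes = (2, 3, 4)
        m = T.tmean(x, axis=axes, keepdims=True)
        centered = x + T.mul(m, -1.0)
        var = T.tmean(T.power(centered, 2.0), axis=axes, keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return T.mul(T.mul(centered, inv), self.gamma) + self.beta


class LayerNorm(Module):
    """Normalization over the trailing feature dimension."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        m = T.tmean(x, axis=-1, keepdims=True)
        centered = x + T.mul(m, -1.0)
        var = T.tmean(T.power(centered, 2.0), axis=-1, keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return T.mul(T.mul(centered, inv), self.gamma) + self.beta
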