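"""Layer abstractions on top of the autodiff tensor engine."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    conv3d,
    instance_norm3d,
    layer_norm,
    leaky_relu,
    matmul,
)

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal module container: parameter registration and traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(key)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: np.array(p.data) for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]} ...")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


# ----------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


def _trunc_normal(rng: np.random.Generator, shape, std=0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "trunc_normal"):
        if init == "trunc_normal":
            w = _trunc_normal(rng, (in_features, out_features))
        elif init == "zero":
            w = np.zeros((in_features, out_features), dtype=DTYPE)
        else:
            w = _kaiming(rng, in_features, (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 init: str = "kaiming"):
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel**3
        if init == "zero":
            w = np.zeros((out_ch, in_ch, kernel, kernel, kernel), dtype=DTYPE)
        else:
            w = _kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm3d(x, self.gamma, self.beta, self.eps)


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class ConvBlock(Module):
    """Two (3x3x3 conv -> instance norm -> leaky ReLU) units with a residual add.

    When the channel counts differ the residual path uses a 1x1x1
    projection; with a stride the projection is strided too.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1, slope: float = 0.01):
        self.slope = slope
        self.conv1 = Conv3d(in_ch, out_ch, 3, rng, stride=stride)
        self.norm1 = InstanceNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, 3, rng)
        self.norm2 = InstanceNorm3d(out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = Conv3d(in_ch, out_ch, 1, rng, stride=stride, padding=0, bias=False)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.norm1(self.conv1(x)), self.slope)
        h = self.norm2(self.conv2(h))
        res = x if self.proj is None else self.proj(x)
        return leaky_relu(h + res, self.slope)
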