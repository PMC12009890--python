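"""Neural-network building blocks on top of the autodiff engine.

Mirrors the familiar Module/Parameter idiom: a :class:`Module` owns named
parameters and sub-modules, exposes ``parameters()`` / ``state_dict()`` and is
callable.  Checkpoints are plain ``.npz`` archives keyed by dotted parameter
paths, so they are portable and inspectable.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2x2

__all__ = [
    "Conv2d",
    "LayerNorm",
    "Linear",
    "MaxPool2x2",
    "Module",
    "Parameter",
    "ReLU",
    "Sequential",
    "load_checkpoint",
    "save_checkpoint",
]


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- registry -------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


def save_checkpoint(module: Module, path) -> None:
    np.savez(path, **module.state_dict())


def load_checkpoint(module: Module, path) -> None:
    with np.load(path) as archive:
        module.load_state_dict({k: archive[k] for k in archive.files})


# -- initialization -----------------------------------------------------------

def init_weight(shape, fan_in: int, rng: np.random.Generator, scheme: str = "he"):
    """Draw initial weights: 'he' (Kaiming normal) or 'gaussian' (std 0.1)."""
    if scheme == "he":
        std = math.sqrt(2.0 / fan_in)
    elif scheme == "gaussian":
        std = 0.1
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return rng.normal(0.0, std, size=shape)


# -- layers -------------------------------------------------------------------

class Conv2d(Module):
    """Stride-1 convolution with 'same' padding by default.

    Padding defaults to ``((k - 1) * dilation) // 2`` which preserves the
    spatial size for odd kernels.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        padding: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        scheme: str = "he",
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        k = int(kernel_size)
        fan_in = in_channels * k * k
        self.weight = Parameter(
            init_weight((out_channels, in_channels, k, k), fan_in, rng, scheme)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.kernel_size = k
        self.dilation = int(dilation)
        self.padding = ((k - 1) * self.dilation) // 2 if padding is None else int(padding)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        scheme: str = "he",
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(
            init_weight((in_features, out_features), in_features, rng, scheme)
        )
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalization over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
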