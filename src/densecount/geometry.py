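"""Analytic tools for designing cascades of dilated convolutions.

Three questions arise when stacking dilated convolutions for counting
networks: how large is the receptive field after each layer, do the chosen
dilation rates avoid the gridding artefact (holes in the set of input pixels
that reach an output unit), and how many input pixels actually contribute.
These are pure functions of the layer schedule and are used both to document
the counting network's columns and to validate their dilation choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "Schedule",
    "effective_extent",
    "gridding_coverage",
    "hdc_valid",
    "receptive_field_schedule",
]


@dataclass(frozen=True)
class LayerSpec:
    """One convolution layer: odd kernel side, dilation rate, stride."""

    kernel: int
    dilation: int = 1
    stride: int = 1

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


@dataclass(frozen=True)
class Schedule:
    """An ordered cascade of convolution layers."""

    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("schedule must contain at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @classmethod
    def uniform(cls, kernel: int, dilations: Sequence[int], strides: Sequence[int] | None = None):
        strides = strides if strides is not None else [1] * len(dilations)
        return cls(tuple(LayerSpec(kernel, d, s) for d, s in zip(dilations, strides)))


def effective_extent(kernel: int, dilation: int) -> int:
    """Side length of a dilated kernel's footprint: K + (K - 1)(D - 1).

    A k-tap kernel with dilation d places taps d apart, spanning
    (k - 1) * d + 1 input pixels.
    """
    if kernel < 1 or dilation < 1:
        raise ValueError("kernel and dilation must be positive")
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    return kernel + (kernel - 1) * (dilation - 1)


def receptive_field_schedule(schedule: Schedule) -> list[int]:
    """Per-layer receptive-field sides via r_n = r_{n-1} + (R_n - 1) * prod(s_i, i<n)."""
    sides: list[int] = []
    r = 1
    stride_prod = 1
    for layer in schedule.layers:
        extent = effective_extent(layer.kernel, layer.dilation)
        r = r + (extent - 1) * stride_prod
        sides.append(r)
        stride_prod *= layer.stride
    return sides


def hdc_valid(dilations: Sequence[int]) -> bool:
    """Hybrid-dilated-convolution rule: the rates must not share a common factor.

    Treats the whole list as one group; valid iff gcd over all rates is 1
    (a single layer with rate 1 is trivially valid).
    """
    rates = list(dilations)
    if not rates:
        raise ValueError("dilation list must be non-empty")
    if any(r < 1 for r in rates):
        raise ValueError("dilation rates must be >= 1")
    return math.gcd(*rates) == 1 if len(rates) > 1 else rates[0] == 1


def gridding_coverage(schedule: Schedule) -> tuple[int, int]:
    """Brute-force count of input pixels that reach one output pixel.

    Propagates a binary support mask backwards through the cascade (stride-1
    layers): starting from a single output pixel, each layer dilates the
    support by its kernel's tap offsets.  Returns ``(used, footprint)`` where
    ``used`` is the number of contributing input pixels and ``footprint`` the
    full receptive-field square.
    """
    for layer in schedule.layers:
        if layer.stride != 1:
            raise NotImplementedError("gridding analysis is defined for stride-1 cascades")
    support = np.ones((1, 1), dtype=np.int64)
    for layer in schedule.layers:
        extent = effective_extent(layer.kernel, layer.dilation)
        taps = np.zeros((extent, extent), dtype=np.int64)
        taps[:: layer.dilation, :: layer.dilation] = 1
        # Minkowski sum of the support with the tap pattern
        from scipy.signal import convolve2d

        support = (convolve2d(support, taps, mode="full") > 0).astype(np.int64)
    used = int(support.sum())
    footprint = int(support.shape[0] * support.shape[1])
    return used, footprint
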