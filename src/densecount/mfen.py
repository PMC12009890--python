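"""Multiscale feature-enhancement counting network.

The counter regresses a stride-8 density map from an RGB image.  A VGG-16
style front end (first 10 convolutions, three 2x poolings) extracts shared
features; three parallel columns then process them with cascades of dilated
residual modules whose kernel sizes (3 / 5 / 9) and hybrid dilation
schedules give each column a different receptive-field ladder (the schedules
are exactly the validated hybrid-dilation sets -- within a column the rates
share no common factor, so stacked dilations leave no gridding holes).  Each
column ends in a channel+spatial attention block (CBAM); the three refined
maps are fused by element-wise summation and a 1x1 head produces the
non-negative density map whose element sum is the predicted count.

Dilated residual modules, with C the column width:

* ``DRM1``: three 1x1 convolutions (a: in->C/4, b: C/4->C/4, residual:
  in->C) and one k x k dilated convolution C/4->C/2; the output concatenates
  [dilated(b(a(F))), a(F), b(a(F))] (C/2 + C/4 + C/4 = C channels) and adds
  the residual.  The a/b outputs are shared between the dilated path and the
  concat branches.
* ``DRM2``: 1x1 pre: C->C/2 shared by a k x k dilated C/2->C/2 path and the
  concat branch, plus a 1x1 residual C->C.
* ``DRM3``: k x k dilated C->C plus a 1x1 residual C->C.

ReLU follows every convolution except the attention logits and the final
head (clamped at zero); no batch normalisation is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, maxpool2x2
from .geometry import hdc_valid
from .io import DensityMap
from .nn import Conv2d, Linear, Module

__all__ = [
    "CBAM",
    "DRM1",
    "DRM2",
    "DRM3",
    "Frontend",
    "MFEN",
    "MFENConfig",
    "count_from_density",
    "count_parameters",
    "mfen_forward",
]

OUTPUT_STRIDE = 8


@dataclass(frozen=True)
class MFENConfig:
    """Architecture plan; fully determines the trainable parameter count."""

    column_kernels: tuple[int, int, int] = (3, 5, 9)
    dilation_schedules: tuple[tuple[int, ...], ...] = (
        (1, 3, 7, 1, 3),
        (1, 5, 13, 1, 5),
        (1, 9, 17, 1, 9),
    )
    column_width: int = 160
    frontend_channels: int = 512
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def __post_init__(self):
        if len(self.column_kernels) != 3 or len(self.dilation_schedules) != 3:
            raise ValueError("three columns are required")
        for k in self.column_kernels:
            if k % 2 == 0:
                raise ValueError("column kernels must be odd")
        for schedule in self.dilation_schedules:
            if len(schedule) != 5:
                raise ValueError("each dilation schedule must have 5 entries")
            if not hdc_valid(schedule):
                raise ValueError(f"dilation schedule {schedule} violates the HDC rule")
        if self.column_width % 4:
            raise ValueError("column width must be divisible by 4")
        if self.column_width % self.cbam_reduction:
            raise ValueError("column width must be divisible by the CBAM reduction")
        if self.frontend_channels % 8:
            raise ValueError("frontend base width must be divisible by 8")
        if self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("CBAM spatial kernel must be odd")

    @property
    def frontend_plan(self) -> tuple[int, ...]:
        w = self.frontend_channels
        return (w // 8, w // 8, w // 4, w // 4, w // 2, w // 2, w // 2, w, w, w)


class Frontend(Module):
    """First 10 convolutions of the VGG-16 topology, 2x pools after 2, 4, 7."""

    POOL_AFTER = (2, 4, 7)

    def __init__(self, plan: tuple[int, ...], rng, scheme: str = "he"):
        channels = 3
        self.convs = []
        for width in plan:
            self.convs.append(Conv2d(channels, width, 3, rng=rng, scheme=scheme))
            channels = width
        self.out_channels = channels

    def forward(self, x: Tensor) -> Tensor:
        for i, conv in enumerate(self.convs, start=1):
            x = conv(x).relu()
            if i in self.POOL_AFTER:
                x = maxpool2x2(x)
        return x


class DRM1(Module):
    def __init__(self, in_channels: int, width: int, kernel: int, dilation: int, rng, scheme="he"):
        if width % 4:
            raise ValueError("column width must be divisible by 4")
        q = width // 4
        self.a = Conv2d(in_channels, q, 1, rng=rng, scheme=scheme)
        self.b = Conv2d(q, q, 1, rng=rng, scheme=scheme)
        self.dilated = Conv2d(q, width // 2, kernel, dilation=dilation, rng=rng, scheme=scheme)
        self.residual = Conv2d(in_channels, width, 1, rng=rng, scheme=scheme)

    def forward(self, x: Tensor) -> Tensor:
        fa = self.a(x).relu()
        fb = self.b(fa).relu()
        fd = self.dilated(fb).relu()
        return concat([fd, fa, fb], axis=1) + self.residual(x).relu()


class DRM2(Module):
    def __init__(self, width: int, kernel: int, dilation: int, rng, scheme="he"):
        if width % 2:
            raise ValueError("column width must be even")
        half = width // 2
        self.pre = Conv2d(width, half, 1, rng=rng, scheme=scheme)
        self.dilated = Conv2d(half, half, kernel, dilation=dilation, rng=rng, scheme=scheme)
        self.residual = Conv2d(width, width, 1, rng=rng, scheme=scheme)

    def forward(self, x: Tensor) -> Tensor:
        fp = self.pre(x).relu()
        fd = self.dilated(fp).relu()
        return concat([fd, fp], axis=1) + self.residual(x).relu()


class DRM3(Module):
    def __init__(self, width: int, kernel: int, dilation: int, rng, scheme="he"):
        self.dilated = Conv2d(width, width, kernel, dilation=dilation, rng=rng, scheme=scheme)
        self.residual = Conv2d(width, width, 1, rng=rng, scheme=scheme)

    def forward(self, x: Tensor) -> Tensor:
        return self.dilated(x).relu() + self.residual(x).relu()


class CBAM(Module):
    """Channel-then-spatial multiplicative attention with sigmoid gates."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7, rng=None, scheme="he"):
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng, scheme=scheme)
        self.fc2 = Linear(hidden, channels, rng=rng, scheme=scheme)
        self.spatial = Conv2d(2, 1, spatial_kernel, rng=rng, scheme=scheme)

    def _channel_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))  # (N, C)
        mx = x.max(axis=(2, 3))
        logits = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        n, c = logits.shape
        return logits.sigmoid().reshape(n, c, 1, 1)

    def _spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.spatial(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = x * self._channel_gate(x)
        return x * self._spatial_gate(x)


class Column(Module):
    """DRM1 x3 -> DRM2 -> DRM3 -> CBAM with one kernel size and dilation ladder."""

    def __init__(self, in_channels: int, config: MFENConfig, index: int, rng, scheme="he"):
        k = config.column_kernels[index]
        d = config.dilation_schedules[index]
        width = config.column_width
        self.blocks = [
            DRM1(in_channels, width, k, d[0], rng, scheme),
            DRM1(width, width, k, d[1], rng, scheme),
            DRM1(width, width, k, d[2], rng, scheme),
            DRM2(width, k, d[3], rng, scheme),
            DRM3(width, k, d[4], rng, scheme),
        ]
        self.cbam = CBAM(width, config.cbam_reduction, config.cbam_spatial_kernel, rng, scheme)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.cbam(x)


class MFEN(Module):
    """Full counting network: frontend -> three columns -> sum fusion -> 1x1 head."""

    def __init__(self, config: MFENConfig = MFENConfig(), rng=None, scheme: str = "he"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.frontend = Frontend(config.frontend_plan, rng, scheme)
        self.columns = [
            Column(self.frontend.out_channels, config, i, rng, scheme) for i in range(3)
        ]
        self.head = Conv2d(config.column_width, 1, 1, rng=rng, scheme=scheme)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) float input -> (N, 1, H/8, W/8) non-negative density."""
        n, c, h, w = x.shape
        if h % OUTPUT_STRIDE or w % OUTPUT_STRIDE:
            raise ValueError("input sides must be divisible by 8 (pad upstream)")
        features = self.frontend(x)
        fused = self.columns[0](features)
        for column in self.columns[1:]:
            fused = fused + column(features)
        return self.head(fused).relu()  # clamp-at-zero head


def mfen_forward(model: MFEN, image: np.ndarray) -> DensityMap:
    """Predict a stride-8 density map for one RGB image (numpy in, numpy out)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    h, w = image.shape[:2]
    pad_h = (-h) % OUTPUT_STRIDE
    pad_w = (-w) % OUTPUT_STRIDE
    if pad_h or pad_w:
        image = np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    out = model(Tensor(image.transpose(2, 0, 1)[None])).data[0, 0]
    gh, gw = math.ceil(h / OUTPUT_STRIDE), math.ceil(w / OUTPUT_STRIDE)
    return DensityMap(out[:gh, :gw], OUTPUT_STRIDE, (w, h))


def count_from_density(dmap: DensityMap | np.ndarray) -> float:
    """The count is the element sum of the density map."""
    values = dmap.values if isinstance(dmap, DensityMap) else np.asarray(dmap)
    return float(values.sum())


def count_parameters(config: MFENConfig = MFENConfig()) -> int:
    """Exact trainable-scalar count of the instantiated model."""
    return MFEN(config, rng=np.random.default_rng(0)).num_parameters()
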