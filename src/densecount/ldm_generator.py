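"""Learnable density-map (LDM) ground truth.

Instead of smoothing annotations with a hand-chosen Gaussian, a windowed-
attention encoder maps the RGB image to a per-location *kernel map*: at every
stride-8 grid cell it predicts a k^2 vector encoding a k x k kernel.  For each
annotated point the vector at its cell is clamped at zero, normalised to sum
to one and stamped onto the map.  Because every stamped kernel sums to one,
the map integrates exactly to the annotation count *for any generator
weights* -- training can reshape the mass around each fruit (to match its
size, pose and occlusion) but can never change the count.

The encoder follows the hierarchical windowed-attention design: 4x4 patch
embedding, a first group of transformer blocks, a 2x down-merge, then two
further groups at stride 8, with the second group's output added to the
third group's output before a linear head to k^2 channels.  Attention is
restricted to M x M windows, alternating between regular and half-window-
shifted partitions; masking keeps shifted-window attention strictly
intra-window.  No relative position bias is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .autodiff import Tensor, embed, matmul, softmax
from .dmg_classical import normalize_kernel, place_kernels
from .io import DensityMap, PointSet
from .nn import LayerNorm, Linear, Module

__all__ = [
    "KernelGenerator",
    "SwinBlock",
    "SwinConfig",
    "generate_kernel_map",
    "ldm_ground_truth",
    "stamp_kernel_map",
]

OUTPUT_STRIDE = 8


@dataclass(frozen=True)
class SwinConfig:
    """Kernel-generator hyperparameters.

    ``embed_dim`` is the patch-embedding width c (stages run at c, 2c, 2c);
    ``window`` the attention window side M in tokens; ``kernel_k`` the odd
    side of the predicted kernels (k^2 output channels).
    """

    patch_size: int = 4
    embed_dim: int = 96
    window: int = 8
    depths: tuple[int, int, int] = (2, 2, 2)
    heads: tuple[int, int, int] = (3, 6, 6)
    kernel_k: int = 7

    def __post_init__(self):
        if self.patch_size != 4:
            raise ValueError("patch_size is fixed at 4")
        if len(self.depths) != 3 or len(self.heads) != 3:
            raise ValueError("exactly three transformer groups are required")
        if self.kernel_k < 1 or self.kernel_k % 2 == 0:
            raise ValueError("kernel_k must be odd")
        dims = (self.embed_dim, 2 * self.embed_dim, 2 * self.embed_dim)
        for dim, h in zip(dims, self.heads):
            if dim % h:
                raise ValueError(f"stage width {dim} not divisible by {h} heads")


# -- window bookkeeping -------------------------------------------------------

def _space_to_depth(x: Tensor, factor: int) -> Tensor:
    n, h, w, c = x.shape
    x = x.reshape(n, h // factor, factor, w // factor, factor, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, h // factor, w // factor, factor * factor * c)


def _partition_windows(x: Tensor, m: int) -> Tensor:
    n, h, w, c = x.shape
    x = x.reshape(n, h // m, m, w // m, m, c).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n * (h // m) * (w // m), m * m, c)


def _merge_windows(x: Tensor, m: int, n: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(n, h // m, w // m, m, m, c).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, h, w, c)


@lru_cache(maxsize=32)
def _shift_mask(hp: int, wp: int, m: int, shift: int) -> np.ndarray:
    """Additive mask (n_windows, m^2, m^2): -inf between wrapped regions."""
    regions = np.zeros((hp, wp))
    rid = 0
    for hslice in (slice(0, -m), slice(-m, -shift), slice(-shift, None)):
        for wslice in (slice(0, -m), slice(-m, -shift), slice(-shift, None)):
            regions[hslice, wslice] = rid
            rid += 1
    win = (
        regions.reshape(hp // m, m, wp // m, m)
        .transpose(0, 2, 1, 3)
        .reshape(-1, m * m)
    )
    mask = np.where(win[:, None, :] != win[:, :, None], -np.inf, 0.0)
    return mask


class WindowAttention(Module):
    """Multi-head self-attention within M x M windows."""

    def __init__(self, dim: int, heads: int, rng, scheme: str = "he"):
        self.qkv = Linear(dim, 3 * dim, rng=rng, scheme=scheme)
        self.proj = Linear(dim, dim, rng=rng, scheme=scheme)
        self.heads = heads
        self.dim = dim
        self.last_attention: np.ndarray | None = None  # (B, heads, T, T), detached

    def forward(self, xw: Tensor, mask: np.ndarray | None) -> Tensor:
        b, t, c = xw.shape
        h = self.heads
        dh = c // h
        qkv = self.qkv(xw).reshape(b, t, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, t, dh)
        logits = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            nw = mask.shape[0]
            tiled = np.tile(mask, (b // nw, 1, 1))[:, None]  # (b, 1, t, t)
            logits = logits + Tensor(tiled)
        attn = softmax(logits, axis=-1)
        self.last_attention = attn.data.copy()
        out = matmul(attn, v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """Pre-norm residual block: x + WMSA(LN(x)), then + MLP(LN(.)).

    ``shift=True`` cyclically shifts the grid by window/2 before windowing and
    masks attention across the wrap boundary.
    """

    def __init__(self, dim: int, heads: int, window: int, shift: bool, rng, scheme="he"):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng, scheme)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 4 * dim, rng=rng, scheme=scheme)
        self.fc2 = Linear(4 * dim, dim, rng=rng, scheme=scheme)
        self.window = window
        self.shift = window // 2 if shift else 0

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        m = self.window
        if m > h or m > w:
            raise ValueError(f"window {m} exceeds feature side {h}x{w}")
        pad_h = (-h) % m
        pad_w = (-w) % m
        hp, wp = h + pad_h, w + pad_w
        shortcut = x
        y = self.norm1(x)
        if pad_h or pad_w:
            y = embed(y, (n, hp, wp, c), (0, 0, 0, 0))
        s = self.shift
        mask = None
        if s:
            y = y.roll((-s, -s), (1, 2))
            mask = _shift_mask(hp, wp, m, s)
        yw = _partition_windows(y, m)
        yw = self.attn(yw, mask)
        y = _merge_windows(yw, m, n, hp, wp)
        if s:
            y = y.roll((s, s), (1, 2))
        if pad_h or pad_w:
            y = y[:, :h, :w, :]
        x = shortcut + y
        return x + self._mlp(self.norm2(x))


class KernelGenerator(Module):
    """RGB image -> per-location kernel map at output stride 8."""

    def __init__(self, config: SwinConfig = SwinConfig(), rng=None, scheme: str = "he"):
        rng = rng if rng is not None else np.random.default_rng(0)
        c = config.embed_dim
        w = config.window
        self.config = config
        self.embed = Linear(3 * config.patch_size**2, c, rng=rng, scheme=scheme)
        self.embed_norm = LayerNorm(c)
        self.stage1 = [
            SwinBlock(c, config.heads[0], w, shift=bool(i % 2), rng=rng, scheme=scheme)
            for i in range(config.depths[0])
        ]
        self.merge_norm = LayerNorm(4 * c)
        self.merge = Linear(4 * c, 2 * c, bias=False, rng=rng, scheme=scheme)
        self.stage2 = [
            SwinBlock(2 * c, config.heads[1], w, shift=bool(i % 2), rng=rng, scheme=scheme)
            for i in range(config.depths[1])
        ]
        self.stage3 = [
            SwinBlock(2 * c, config.heads[2], w, shift=bool(i % 2), rng=rng, scheme=scheme)
            for i in range(config.depths[2])
        ]
        self.head_norm = LayerNorm(2 * c)
        self.head = Linear(2 * c, config.kernel_k**2, rng=rng, scheme=scheme)

    def forward(self, images: Tensor) -> Tensor:
        """(N, H, W, 3) float image batch -> (N, H/8, W/8, k^2) kernel map."""
        n, h, w, c = images.shape
        if c != 3:
            raise ValueError("expected RGB input (N, H, W, 3)")
        if h % OUTPUT_STRIDE or w % OUTPUT_STRIDE:
            raise ValueError("input sides must be divisible by 8 (pad upstream)")
        x = _space_to_depth(images, self.config.patch_size)
        x = self.embed_norm(self.embed(x))
        for block in self.stage1:
            x = block(x)
        x = self.merge(self.merge_norm(_space_to_depth(x, 2)))
        for block in self.stage2:
            x = block(x)
        out2 = x
        for block in self.stage3:
            x = block(x)
        x = out2 + x  # integrate group-2 output with group-3 output
        return self.head(self.head_norm(x))


def _prepare_image(image: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Normalise to float [0, 1] and reflect-pad sides to a multiple of 8."""
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
    return image, h, w


def generate_kernel_map(model: KernelGenerator, image: np.ndarray) -> np.ndarray:
    """Run the generator on one image; returns an (H/8, W/8, k^2) array."""
    padded, h, w = _prepare_image(image)
    out = model(Tensor(padded[None])).data[0]
    gh = math.ceil(h / OUTPUT_STRIDE)
    gw = math.ceil(w / OUTPUT_STRIDE)
    return out[:gh, :gw]


def ldm_ground_truth(model: KernelGenerator, image: np.ndarray, points: PointSet) -> DensityMap:
    """Stride-8 GT density map: normalised per-point kernels from the kernel map.

    Conservation holds for arbitrary generator weights: each kernel is
    normalised to sum to one before stamping.
    """
    kmap = generate_kernel_map(model, image)
    kernels = [
        normalize_kernel(kmap[int(y // OUTPUT_STRIDE), int(x // OUTPUT_STRIDE)])
        for x, y in points.points
    ]
    return place_kernels(points, kernels, kmap.shape[:2], OUTPUT_STRIDE)


def stamp_kernel_map(kmap: Tensor, points: PointSet, stride: int = OUTPUT_STRIDE) -> Tensor:
    """Differentiable stamping of a kernel-map Tensor into a density-map Tensor.

    Mirrors :func:`ldm_ground_truth` (clamp, normalise, border renormalise)
    but keeps the graph alive so the joint loss backpropagates into the
    generator.  ``kmap``: (Hg, Wg, k^2); returns (Hg, Wg).
    """
    gh, gw, ch = kmap.shape
    k = math.isqrt(ch)
    if k * k != ch or k % 2 == 0:
        raise ValueError("kernel-map channel count must be an odd square")
    r = (k - 1) // 2
    out = Tensor(np.zeros((gh, gw)))
    for x, y in points.points:
        gx, gy = int(x // stride), int(y // stride)
        if not (0 <= gx < gw and 0 <= gy < gh):
            raise ValueError(f"point ({x}, {y}) falls outside the kernel map")
        vec = kmap[gy, gx]
        clamped = vec.relu()
        total = float(clamped.data.sum())
        if total <= 0.0:
            kern = Tensor(np.full((k, k), 1.0 / (k * k)))  # uniform fallback
        else:
            kern = (clamped / clamped.sum()).reshape(k, k)
        y0, y1 = max(0, gy - r), min(gh, gy + r + 1)
        x0, x1 = max(0, gx - r), min(gw, gx + r + 1)
        sub = kern[y0 - (gy - r) : y1 - (gy - r), x0 - (gx - r) : x1 - (gx - r)]
        mass = float(sub.data.sum())
        if mass <= 0.0:
            delta = np.zeros((gh, gw))
            delta[gy, gx] = 1.0
            out = out + Tensor(delta)
        else:
            out = out + embed(sub / sub.sum(), (gh, gw), (y0, x0))
    return out
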