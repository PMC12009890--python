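"""Joint optimisation of the kernel generator and the counting network.

Each step builds the ground-truth density map from the *current* generator
weights (differentiably, via :func:`densecount.ldm_generator.stamp_kernel_map`),
runs the counter, and minimises

    loss = sum_i ||Mhat_i - M_i||^2 + lambda * sum_i (1 - CS(Mhat_i, M_i))

where CS is cosine similarity between the flattened maps with a zeta guard
against zero norms.  One Adam optimiser updates the union of both models'
parameters simultaneously; because every stamped kernel is normalised, the
generator can reshape the target mass but never alter the per-image count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .io import PointSet
from .ldm_generator import KernelGenerator, stamp_kernel_map
from .mfen import MFEN
from .nn import Parameter

__all__ = [
    "Adam",
    "LossValue",
    "TrainConfig",
    "augment",
    "cosine_similarity",
    "joint_loss",
    "train_joint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults follow the reference protocol (Adam, batch 8, lr 7e-6, L2
    1e-4, 200 epochs); the cosine weight ``lam`` is exposed because no
    canonical value exists for it.
    """

    lr: float = 7e-6
    weight_decay: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    lam: float = 1.0
    zeta: float = 1e-8
    seed: int = 0
    hflip: bool = True
    brightness: bool = True
    gaussian_noise: bool = True

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class LossValue:
    """total = l2_term + lam * cosine_term."""

    total: float
    l2_term: float
    cosine_term: float


class Adam:
    """Adam with decoupled-from-nothing classic L2 regularisation on the gradient."""

    def __init__(self, params: list[Parameter], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# -- loss ---------------------------------------------------------------------

def cosine_similarity(a, b, zeta: float = 1e-8):
    """dot(a, b) / max(||a|| * ||b||, zeta) on flattened maps.

    Accepts numpy arrays (returns float) or Tensors (returns a Tensor kept in
    the graph; the guard branch treats the denominator as a constant).
    """
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        af = a.reshape(a.size)
        bf = b.reshape(b.size)
        dot = (af * bf).sum()
        norm_prod = ((af * af).sum() ** 0.5) * ((bf * bf).sum() ** 0.5)
        if float(norm_prod.data) < zeta:
            return dot * (1.0 / zeta)
        return dot / norm_prod
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    denom = max(np.linalg.norm(a) * np.linalg.norm(b), zeta)
    return float(a @ b / denom)


def joint_loss(estimated, generated_gt, lam: float = 1.0, zeta: float = 1e-8):
    """Batch loss: l2_term = sum_i ||Mhat_i - M_i||^2, cosine_term = sum_i (1 - CS_i).

    ``estimated`` and ``generated_gt`` are equal-length sequences of 2-D maps
    (numpy arrays or Tensors).  Returns ``(total, LossValue)`` where ``total``
    is a Tensor usable for backprop and LossValue carries the float terms.
    """
    if len(estimated) != len(generated_gt):
        raise ValueError("batch size mismatch")
    l2 = Tensor(0.0)
    cos = Tensor(0.0)
    for mhat, m in zip(estimated, generated_gt):
        mhat = mhat if isinstance(mhat, Tensor) else Tensor(mhat)
        m = m if isinstance(m, Tensor) else Tensor(m)
        if mhat.shape != m.shape:
            raise ValueError(f"map shape mismatch: {mhat.shape} vs {m.shape}")
        diff = mhat - m
        l2 = l2 + (diff * diff).sum()
        cos = cos + (1.0 - cosine_similarity(mhat, m, zeta))
    total = l2 + lam * cos
    value = LossValue(total=float(total.data), l2_term=float(l2.data), cosine_term=float(cos.data))
    if not math.isfinite(value.total):
        raise FloatingPointError(f"non-finite loss: {value}")
    return total, value


# -- augmentation -------------------------------------------------------------

def augment(
    image: np.ndarray,
    points: PointSet,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PointSet]:
    """Random horizontal flip, brightness scaling and Gaussian noise.

    Each transform fires independently with probability 0.5.  ``image`` is
    float in [0, 1]; the point count is always preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    pts = points.points.copy()
    if config.hflip and rng.random() < 0.5:
        image = image[:, ::-1].copy()
        # pixel-center mirror; sub-pixel coords beyond W-1 clamp at the edge
        pts[:, 0] = np.clip(points.image_width - 1 - pts[:, 0], 0.0, None)
    if config.brightness and rng.random() < 0.5:
        image = np.clip(image * rng.uniform(0.8, 1.2), 0.0, 1.0)
    if config.gaussian_noise and rng.random() < 0.5:
        image = np.clip(image + rng.normal(0.0, 5.0 / 255.0, size=image.shape), 0.0, 1.0)
    return image, PointSet(pts, points.image_width, points.image_height, points.source_id)


# -- joint training -----------------------------------------------------------

def train_joint(
    dataset: list[tuple[np.ndarray, PointSet]],
    generator: KernelGenerator,
    counter: MFEN,
    config: TrainConfig,
    steps: int | None = None,
    lr: float | None = None,
    val_dataset: list[tuple[np.ndarray, PointSet]] | None = None,
) -> list[dict]:
    """Jointly train generator and counter; returns the per-step log.

    ``steps`` caps the number of optimiser updates (otherwise
    ``config.epochs`` passes over the dataset are run).  Deterministic given
    ``config.seed``.  Each log record carries the loss terms and the worst
    deviation of a GT-map integral from its annotation count in the batch.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    params = generator.parameters() + counter.parameters()
    optimizer = Adam(params, lr=lr if lr is not None else config.lr,
                     weight_decay=config.weight_decay)
    log: list[dict] = []
    step = 0
    max_steps = steps if steps is not None else config.epochs * max(
        1, len(dataset) // config.batch_size
    )
    while step < max_steps:
        order = rng.permutation(len(dataset))
        for start in range(0, len(order), config.batch_size):
            if step >= max_steps:
                break
            batch = [dataset[i] for i in order[start : start + config.batch_size]]
            optimizer.zero_grad()
            estimated, targets, gt_errs = [], [], []
            for image, points in batch:
                image = image.astype(np.float64) / 255.0 if image.dtype == np.uint8 else image
                image, points = augment(image, points, config, rng)
                kmap = generator(Tensor(image[None]))[0]
                gt = stamp_kernel_map(kmap, points)
                gt_errs.append(abs(float(gt.data.sum()) - points.count))
                est = counter(Tensor(image.transpose(2, 0, 1)[None]))[0, 0]
                estimated.append(est)
                targets.append(gt)
            total, value = joint_loss(estimated, targets, lam=config.lam, zeta=config.zeta)
            total.backward()
            gen_grad = math.sqrt(
                sum(float((p.grad**2).sum()) for p in generator.parameters() if p.grad is not None)
            )
            optimizer.step()
            step += 1
            record = {
                "step": step,
                "total": value.total,
                "l2_term": value.l2_term,
                "cosine_term": value.cosine_term,
                "max_gt_count_error": max(gt_errs),
                "generator_grad_norm": gen_grad,
            }
            if val_dataset and step == max_steps:
                record["val_mae"] = _validation_mae(val_dataset, counter)
            log.append(record)
    return log


def _validation_mae(dataset, counter: MFEN) -> float:
    from .mfen import mfen_forward

    errs = [
        abs(mfen_forward(counter, image).count - points.count)
        for image, points in dataset
    ]
    return float(np.mean(errs))


def default_tiny_configs() -> tuple:
    """Scaled-down model pair used for CPU smoke training (tiny widths)."""
    from .ldm_generator import SwinConfig
    from .mfen import MFENConfig

    swin = SwinConfig(embed_dim=24, window=4, depths=(1, 1, 1), heads=(3, 6, 6), kernel_k=5)
    mfen = MFENConfig(column_width=16, frontend_channels=32, cbam_reduction=4)
    return swin, mfen
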