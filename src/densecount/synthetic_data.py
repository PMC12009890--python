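"""Synthetic clustered-fruit scenes with point annotations.

Real clustered-fruit field imagery shows tight clumps of partially occluded
red fruit against foliage, with per-image counts spanning roughly an order of
magnitude.  This module emulates that statistical structure so the whole
pipeline is exercisable without any field data:

* **Point process**: a Neyman-Scott construction -- cluster parents uniform
  in frame, per-cluster offspring counts truncated-Poisson, isotropic
  Gaussian offsets -- yielding strongly clustered annotations
  (Clark-Evans index < 1).
* **Count bins**: per-image totals are drawn from one of four bins
  (13-68, 69-124, 125-180, 181-235) and splits represent each bin equally.
* **Rendering**: textured green/brown background, red elliptical fruit with
  per-fruit scale/aspect/hue jitter, foliage-coloured partial occluders, and
  a global lighting regime (midday vs dimmer, gradient-lit evening).

What it does NOT emulate: true 3-D canopy geometry, perspective, motion
blur, or inter-image correlation of a real flight campaign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .io import PointSet, write_image, write_point_annotations

__all__ = [
    "BINS",
    "ClusterParams",
    "SceneSpec",
    "generate_dataset",
    "render_scene",
    "sample_points",
]

BINS: tuple[tuple[int, int], ...] = ((13, 68), (69, 124), (125, 180), (181, 235))


@dataclass(frozen=True)
class SceneSpec:
    size: int = 640
    count_bin: tuple[int, int] = (13, 68)
    scale_class: str = "mixed"
    lighting: str = "midday"
    seed: int = 0

    def __post_init__(self):
        if tuple(self.count_bin) not in BINS:
            raise ValueError(f"count_bin must be one of {BINS}")
        if self.scale_class not in ("small", "large", "mixed"):
            raise ValueError("scale_class must be small, large or mixed")
        if self.lighting not in ("midday", "evening"):
            raise ValueError("lighting must be midday or evening")


@dataclass(frozen=True)
class ClusterParams:
    """Neyman-Scott and rendering parameters.

    Defaults give visually dense clumps on a 640 px frame: ~8 fruits per
    cluster spread over ~18 px, small fruit 4-7 px radius, large 10-16 px.
    """

    mu_cluster: float = 8.0
    sigma_cluster: float = 18.0
    radius_small: tuple[int, int] = (4, 7)
    radius_large: tuple[int, int] = (10, 16)
    occluder_prob: float = 0.5
    max_retries: int = 200

    def __post_init__(self):
        if self.mu_cluster <= 0 or self.sigma_cluster <= 0:
            raise ValueError("cluster parameters must be positive")


def sample_points(
    spec: SceneSpec,
    params: ClusterParams = ClusterParams(),
    rng: np.random.Generator | None = None,
) -> PointSet:
    """Draw a clustered point pattern whose total lies in the requested bin."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.count_bin
    target = int(rng.integers(lo, hi + 1))
    points: list[np.ndarray] = []
    total = 0
    for _ in range(params.max_retries):
        center = rng.uniform(0, spec.size, size=2)
        n_offspring = max(1, int(rng.poisson(params.mu_cluster)))
        offsets = rng.normal(0.0, params.sigma_cluster, size=(n_offspring, 2))
        cluster = np.clip(center + offsets, 0.0, spec.size - 1e-6)
        points.append(cluster)
        total += n_offspring
        if total >= target:
            break
    else:
        raise RuntimeError(f"could not reach bin {spec.count_bin} in {params.max_retries} clusters")
    all_points = np.concatenate(points)[:target]
    return PointSet(all_points, spec.size, spec.size, source_id=f"seed{spec.seed}")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency green/brown foliage texture with fine noise, float [0,1]."""
    coarse = rng.random((size // 32 + 1, size // 32 + 1, 3))
    from scipy.ndimage import zoom

    tex = zoom(coarse, (32, 32, 1), order=1)[:size, :size]
    green = np.array([0.18, 0.35, 0.12])
    brown = np.array([0.30, 0.22, 0.10])
    mix = tex[..., :1]
    base = mix * green + (1 - mix) * brown
    base += 0.08 * (tex - 0.5)
    base += rng.normal(0, 0.015, size=base.shape)
    return np.clip(base, 0, 1)


def _fruit_radius(scale_class: str, params: ClusterParams, rng) -> float:
    if scale_class == "mixed":
        scale_class = "small" if rng.random() < 0.5 else "large"
    lo, hi = params.radius_small if scale_class == "small" else params.radius_large
    return float(rng.uniform(lo, hi))


def render_scene(
    points: PointSet,
    spec: SceneSpec,
    params: ClusterParams = ClusterParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render an (size, size, 3) uint8 scene with one fruit per annotation.

    Every annotated center lies inside its rendered ellipse; occluders are
    offset from the center so they never cover it.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    size = spec.size
    img = _background(size, rng)
    for x, y in points.points:
        radius = _fruit_radius(spec.scale_class, params, rng)
        aspect = rng.uniform(0.6, 1.0)
        rotation = rng.uniform(0, np.pi)
        color = np.array(
            [rng.uniform(0.70, 0.95), rng.uniform(0.12, 0.28), rng.uniform(0.10, 0.22)]
        )
        rr, cc = draw_ellipse(y, x, radius, radius * aspect, shape=(size, size), rotation=rotation)
        img[rr, cc] = color * rng.uniform(0.9, 1.1, size=(len(rr), 1)).clip(0, 1)
        if rng.random() < params.occluder_prob:
            # foliage blob over the fruit's periphery, clear of the center
            angle = rng.uniform(0, 2 * np.pi)
            occ_r = rng.uniform(0.3, 0.6) * radius
            dist = 0.8 * radius + occ_r * 0.5
            oy, ox = y + dist * np.sin(angle), x + dist * np.cos(angle)
            orr, occ_ = draw_ellipse(oy, ox, occ_r, occ_r, shape=(size, size))
            img[orr, occ_] = np.array([0.16, 0.32, 0.10]) * rng.uniform(0.85, 1.15)
    # lighting: global brightness plus a directional gradient
    brightness = 1.0 if spec.lighting == "midday" else 0.75
    ramp = np.linspace(-0.1, 0.1, size)[None, :, None]
    img = np.clip(img * brightness * (1.0 + ramp), 0, 1)
    return (img * 255).round().astype(np.uint8)


def generate_dataset(
    out_dir,
    n_train: int = 1000,
    n_val: int = 100,
    n_test: int = 100,
    seed: int = 0,
    size: int = 640,
    params: ClusterParams = ClusterParams(),
) -> Path:
    """Write a full synthetic dataset: PNGs, annotation JSONs and a manifest.

    Each split allocates its images equally over the four count bins (sizes
    must be divisible by 4).  Regeneration with the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        if n % 4:
            raise ValueError(f"{split} size {n} not divisible by 4 (equal bin allocation)")
        per_bin = n // 4
        index = 0
        split_code = {"train": 0, "val": 1, "test": 2}[split]
        for bin_idx, count_bin in enumerate(BINS):
            for _ in range(per_bin):
                scene_seed = (seed * 10 + split_code) * 100_000 + index
                spec = SceneSpec(size=size, count_bin=count_bin, seed=scene_seed)
                rng = np.random.default_rng([seed, split_code, index])
                points = sample_points(spec, params, rng)
                image = render_scene(points, spec, params, rng)
                stem = f"{split}_{index:05d}"
                write_image(image, out_dir / f"{stem}.png")
                write_point_annotations(points, out_dir / f"{stem}.json")
                manifest.append(
                    {"split": split, "stem": stem, "bin": list(count_bin), "count": points.count}
                )
                index += 1
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "size": size, "entries": manifest}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def load_dataset(data_dir, split: str | None = None) -> list[tuple[np.ndarray, PointSet]]:
    """Read back (image, PointSet) pairs written by :func:`generate_dataset`."""
    from .io import read_image, read_point_annotations

    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    pairs = []
    for entry in manifest["entries"]:
        if split is not None and entry["split"] != split:
            continue
        stem = entry["stem"]
        pairs.append(
            (read_image(data_dir / f"{stem}.png"), read_point_annotations(data_dir / f"{stem}.json"))
        )
    return pairs
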