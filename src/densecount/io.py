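"""Reading and writing of images, point annotations and density maps.

Point annotations follow the Labelme JSON dialect: a top-level object with
``imageWidth``, ``imageHeight`` and a ``shapes`` list whose entries carry
``shape_type == "point"`` and a single ``[x, y]`` coordinate.  Large frames
can be tiled into fixed-size training crops with annotations reassigned to
their tile; density maps round-trip losslessly through ``.npz`` (or ``.h5``)
containers.

Coordinate convention: 0-based, x to the right, y down, pixel centers at
integer coordinates.  Tiles are half-open ``[x0, x0 + tile)``, so a point on
a boundary belongs to the tile with the larger index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "PointSet",
    "load_density_map",
    "read_image",
    "read_point_annotations",
    "save_density_map",
    "tile_image",
    "write_image",
    "write_point_annotations",
]


@dataclass
class PointSet:
    """Per-image object-center annotations in image pixel coordinates."""

    points: np.ndarray  # (N, 2) array of (x, y)
    image_width: int
    image_height: int
    source_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(pts) and (
            (pts[:, 0] < 0).any()
            or (pts[:, 0] >= self.image_width).any()
            or (pts[:, 1] < 0).any()
            or (pts[:, 1] >= self.image_height).any()
        ):
            raise ValueError("point outside image bounds")
        self.points = pts

    @property
    def count(self) -> int:
        return len(self.points)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PointSet)
            and self.image_width == other.image_width
            and self.image_height == other.image_height
            and self.points.shape == other.points.shape
            and np.allclose(self.points, other.points)
        )


@dataclass
class DensityMap:
    """Non-negative grid whose element sum is the object count."""

    values: np.ndarray  # (H, W)
    stride: int  # image pixels per grid cell
    image_size: tuple[int, int] = field(default=None)  # (width, height)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("density map must be non-negative")
        if not np.isfinite(self.values).all():
            raise ValueError("density map must be finite")
        if self.stride not in (1, 8):
            raise ValueError(f"stride must be 1 or 8, got {self.stride}")
        if self.image_size is None:
            h, w = self.values.shape
            self.image_size = (w * self.stride, h * self.stride)
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))

    @property
    def count(self) -> float:
        return float(self.values.sum())


# -- images -------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


# -- point annotations --------------------------------------------------------

def read_point_annotations(path) -> PointSet:
    """Parse a Labelme-style JSON annotation file into a :class:`PointSet`.

    Non-point shapes are skipped with a warning; malformed point records
    raise ``ValueError`` naming the offending record.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
        shapes = doc["shapes"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing imageWidth/imageHeight/shapes") from exc
    points = []
    for i, shape in enumerate(shapes):
        kind = shape.get("shape_type")
        if kind != "point":
            logger.warning("%s: shape %d has type %r, skipping", path, i, kind)
            continue
        try:
            (x, y), = shape["points"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed point record at shape {i}") from exc
        points.append((float(x), float(y)))
    return PointSet(np.array(points).reshape(-1, 2), width, height, source_id=path.stem)


def write_point_annotations(points: PointSet, path) -> None:
    """Write a :class:`PointSet` as Labelme-style JSON (deterministic bytes)."""
    doc = {
        "imageWidth": int(points.image_width),
        "imageHeight": int(points.image_height),
        "shapes": [
            {
                "label": "fruit",
                "shape_type": "point",
                "points": [[float(x), float(y)]],
            }
            for x, y in points.points
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- tiling -------------------------------------------------------------------

def tile_image(
    image: np.ndarray, points: PointSet, tile: int
) -> list[tuple[np.ndarray, PointSet]]:
    """Cut the largest grid of full ``tile`` x ``tile`` crops and reassign points.

    Margins that do not fit a full tile are discarded; points falling in them
    are dropped (and counted in the log).  Each retained point lands in
    exactly one tile, with coordinates shifted to the tile-local frame.
    """
    height, width = image.shape[:2]
    if tile > width or tile > height:
        raise ValueError(f"tile {tile} larger than image {width}x{height}")
    ncols, nrows = width // tile, height // tile
    tiles: list[tuple[np.ndarray, PointSet]] = []
    dropped = 0
    assigned = [[[] for _ in range(ncols)] for _ in range(nrows)]
    for x, y in points.points:
        col, row = int(x // tile), int(y // tile)
        if col >= ncols or row >= nrows:
            dropped += 1
            continue
        assigned[row][col].append((x - col * tile, y - row * tile))
    for row in range(nrows):
        for col in range(ncols):
            crop = image[row * tile : (row + 1) * tile, col * tile : (col + 1) * tile]
            tiles.append(
                (
                    crop,
                    PointSet(
                        np.array(assigned[row][col]).reshape(-1, 2),
                        tile,
                        tile,
                        source_id=f"{points.source_id}_r{row}c{col}",
                    ),
                )
            )
    if dropped:
        logger.info("tile_image: dropped %d points in discarded margins", dropped)
    return tiles


# -- density map containers ---------------------------------------------------

def save_density_map(dmap: DensityMap, path) -> None:
    """Persist a density map (values stored single-precision)."""
    path = Path(path)
    values = dmap.values.astype(np.float32)
    meta = np.array([dmap.stride, dmap.image_size[0], dmap.image_size[1]], dtype=np.int64)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=values)
            fh.create_dataset("meta", data=meta)
    else:
        np.savez(path, values=values, meta=meta)


def load_density_map(path) -> DensityMap:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        try:
            with h5py.File(path, "r") as fh:
                values = fh["values"][()]
                meta = fh["meta"][()]
        except OSError as exc:
            raise OSError(f"corrupt density-map container: {path}") from exc
    else:
        if not path.suffix:
            path = path.with_suffix(".npz")
        try:
            with np.load(path) as archive:
                values = archive["values"]
                meta = archive["meta"]
        except (OSError, KeyError, ValueError) as exc:
            raise OSError(f"corrupt density-map container: {path}") from exc
    stride, width, height = (int(v) for v in meta)
    return DensityMap(values.astype(np.float64), stride, (width, height))
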