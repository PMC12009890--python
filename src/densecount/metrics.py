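"""Counting accuracy metrics over per-image (ground truth, estimate) pairs.

MAE   = (1/N) sum |C_i - C_i^GT|
RMSE  = sqrt((1/N) sum |C_i - C_i^GT|^2)
SMAPE = (100/N) sum |C_i - C_i^GT| / ((|C_i| + |C_i^GT|) / 2)   [percent]
R^2   = 1 - sum (C_i - C_i^GT)^2 / sum (C_i^GT - mean(C^GT))^2

A SMAPE term with both values zero is defined as 0 (limit convention).
Ground truth for evaluation is the raw annotation count, not the generated
map's integral (identical by conservation, but decoupled for safety).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountRecord",
    "MetricsReport",
    "evaluate",
    "mae",
    "r_squared",
    "rmse",
    "smape",
]


@dataclass(frozen=True)
class CountRecord:
    image_id: str
    gt: float
    est: float

    def __post_init__(self):
        if self.gt < 0:
            raise ValueError("ground-truth count must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    smape_percent: float
    r2: float
    n: int


def _arrays(records: Sequence[CountRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValueError("empty record list")
    gt = np.array([r.gt for r in records], dtype=np.float64)
    est = np.array([r.est for r in records], dtype=np.float64)
    return gt, est


def mae(records: Sequence[CountRecord]) -> float:
    gt, est = _arrays(records)
    return float(np.mean(np.abs(est - gt)))


def rmse(records: Sequence[CountRecord]) -> float:
    gt, est = _arrays(records)
    return float(np.sqrt(np.mean((est - gt) ** 2)))


def smape(records: Sequence[CountRecord]) -> float:
    gt, est = _arrays(records)
    denom = (np.abs(est) + np.abs(gt)) / 2.0
    terms = np.zeros_like(denom)
    nonzero = denom > 0
    terms[nonzero] = np.abs(est - gt)[nonzero] / denom[nonzero]
    return float(100.0 * np.mean(terms))


def r_squared(records: Sequence[CountRecord]) -> float:
    gt, est = _arrays(records)
    ss_tot = float(np.sum((gt - gt.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: all ground-truth counts are equal")
    return float(1.0 - np.sum((est - gt) ** 2) / ss_tot)


def report(records: Sequence[CountRecord]) -> MetricsReport:
    return MetricsReport(
        mae=mae(records),
        rmse=rmse(records),
        smape_percent=smape(records),
        r2=r_squared(records),
        n=len(records),
    )


def evaluate(dataset, model) -> tuple[MetricsReport, pd.DataFrame]:
    """Run the counter on every (image, PointSet) pair and score the counts.

    The estimate is the element sum of the predicted density map; the ground
    truth is the annotation count.  Returns the report and a per-image frame
    (image_id, gt, est, error).
    """
    from .mfen import count_from_density, mfen_forward

    records = [
        CountRecord(
            image_id=points.source_id or str(i),
            gt=float(points.count),
            est=count_from_density(mfen_forward(model, image)),
        )
        for i, (image, points) in enumerate(dataset)
    ]
    frame = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "gt": [r.gt for r in records],
            "est": [r.est for r in records],
            "error": [r.est - r.gt for r in records],
        }
    )
    return report(records), frame
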