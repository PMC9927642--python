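"""Voxel-grid -> farthest-point-sampling hybrid down-sampling.

The raw cloud is first reduced with an axis-aligned voxel grid whose interval
shrinks geometrically until slightly more than the target number of points
survive; FPS then trims the survivors to the exact target. Down-sampling never
invents coordinates: each voxel is represented by the existing input point
nearest the centroid of the voxel's points, so ground-truth labels survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import PointCloud

__all__ = [
    "DownsampleConfig",
    "voxel_grid_filter",
    "farthest_point_sampling",
    "adaptive_downsample",
    "upsample_labels",
]

log = logging.getLogger(__name__)


@dataclass
class DownsampleConfig:
    target_n: int = 15000
    initial_interval: Optional[float] = None  # None -> bbox diagonal / 50
    shrink_factor: float = 0.75
    max_rounds: int = 40
    seed_index: int = 0

    def __post_init__(self) -> None:
        if self.target_n < 1:
            raise ValidationError("target_n must be >= 1")
        if not (0.0 < self.shrink_factor < 1.0):
            raise ValidationError("shrink_factor must be in (0, 1)")
        if self.initial_interval is not None and self.initial_interval <= 0:
            raise ValidationError("initial_interval must be > 0")


def voxel_grid_filter(cloud: PointCloud, interval: float) -> PointCloud:
    """Keep one input point per occupied voxel (nearest to the voxel centroid).

    Voxels are axis-aligned cubes of edge ``interval`` anchored at the cloud's
    minimum corner.
    """
    if interval <= 0:
        raise ValidationError("voxel interval must be > 0")
    if cloud.n < 1:
        raise ValidationError("empty cloud")
    origin = cloud.points.min(axis=0)
    keys = np.floor((cloud.points - origin) / interval).astype(np.int64)
    # group points by voxel key
    order = np.lexsort((np.arange(cloud.n), keys[:, 2], keys[:, 1], keys[:, 0]))
    sk = keys[order]
    boundary = np.ones(cloud.n, dtype=bool)
    boundary[1:] = np.any(sk[1:] != sk[:-1], axis=1)
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], cloud.n)
    chosen = np.empty(len(starts), dtype=np.int64)
    pts = cloud.points
    for vi, (a, b) in enumerate(zip(starts, ends)):
        members = order[a:b]
        centroid = pts[members].mean(axis=0)
        d2 = np.sum((pts[members] - centroid) ** 2, axis=1)
        chosen[vi] = members[int(np.argmin(d2))]
    chosen.sort()
    return cloud.select(chosen)


def farthest_point_sampling(cloud: PointCloud, m: int,
                            seed_index: int = 0) -> PointCloud:
    """Greedy FPS: repeatedly add the point farthest from the selected set.

    Deterministic given ``seed_index``; ties broken by lowest index.
    """
    n = cloud.n
    if not (1 <= m <= n):
        raise ValidationError(f"FPS target m={m} out of range [1, {n}]")
    if m == n:
        return cloud.select(np.arange(n))
    pts = cloud.points
    selected = np.empty(m, dtype=np.int64)
    selected[0] = seed_index
    mind = np.linalg.norm(pts - pts[seed_index], axis=1)
    for j in range(1, m):
        nxt = int(np.argmax(mind))  # argmax returns the first (lowest) index on ties
        selected[j] = nxt
        d = np.linalg.norm(pts - pts[nxt], axis=1)
        np.minimum(mind, d, out=mind)
    return cloud.select(selected)


def adaptive_downsample(cloud: PointCloud,
                        cfg: DownsampleConfig = DownsampleConfig()) -> PointCloud:
    """Voxel-filter with a shrinking interval until > target points survive, then FPS.

    Clouds at or below the target pass through unchanged. If ``max_rounds``
    interval reductions still leave fewer survivors than the target, FPS runs on
    the original cloud instead (logged warning).
    """
    if cloud.n <= cfg.target_n:
        return cloud
    interval = cfg.initial_interval
    if interval is None:
        diag = cloud.bounding_box_diagonal()
        interval = (diag if diag > 0 else 1.0) / 50.0
    filtered = voxel_grid_filter(cloud, interval)
    rounds = 0
    while filtered.n < cfg.target_n and rounds < cfg.max_rounds:
        interval *= cfg.shrink_factor
        filtered = voxel_grid_filter(cloud, interval)
        rounds += 1
    if filtered.n < cfg.target_n:
        log.warning(
            "voxel interval schedule exhausted (%d rounds, %d survivors); "
            "falling back to FPS on the original cloud", rounds, filtered.n,
        )
        filtered = cloud
    return farthest_point_sampling(filtered, cfg.target_n, cfg.seed_index)


def upsample_labels(original: PointCloud, segmented: PointCloud) -> PointCloud:
    """Transfer labels to ``original`` from each point's nearest segmented point."""
    if segmented.labels is None:
        raise ValidationError("segmented cloud has no labels to up-sample")
    tree = cKDTree(segmented.points)
    _, idx = tree.query(original.points, k=1)
    return PointCloud(original.points.copy(), segmented.labels[idx])
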