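"""Leaf instance segmentation of the stem-removed, aligned plant.

A second distance-field clustering pass, anchored at the origin (the stem base,
which is no longer part of the cloud), turns each leaf tip into a cluster core;
hill climbing then pulls every leaf point to its tip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .errors import ValidationError
from .io import PointCloud
from .quickshiftpp import QspConfig, dfsp_segment
from .stem import AlignmentResult

__all__ = ["LeafConfig", "SegmentationResult", "segment_leaves", "assemble_result"]


@dataclass
class LeafConfig:
    k2: int = 32
    beta2: float = 0.85
    alpha2: float = 9.0
    min_core_size: int = 5

    def qsp(self) -> QspConfig:
        return QspConfig(k=self.k2, beta=self.beta2, min_core_size=self.min_core_size)


def segment_leaves(aligned_leaf_cloud: PointCloud,
                   cfg: LeafConfig = LeafConfig()) -> np.ndarray:
    """Per-point leaf instance ids 1..n_l, numbered by descending core size.

    The input must be the stem-removed plant in aligned coordinates (stem base
    at the origin); the origin itself serves as the field base point.
    """
    if aligned_leaf_cloud.n < 1:
        raise ValidationError("empty leaf cloud")
    if aligned_leaf_cloud.n == 1:
        return np.array([1], dtype=np.int64)
    base = np.zeros(3)
    result = dfsp_segment(aligned_leaf_cloud, base, cfg.alpha2, cfg.qsp(),
                          cores_only=False)
    labels = result.labels
    # renumber by descending core size (ties by core id) to 1..n_l
    order = sorted(range(len(result.cores)),
                   key=lambda c: (-result.cores[c].size, c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in labels], dtype=np.int64)


@dataclass
class SegmentationResult:
    """Full-cloud instance labeling plus the artifacts that produced it."""

    labels: np.ndarray            # stem = 0, leaves = 1..n_l (aligned-cloud order)
    alignment: AlignmentResult
    n_leaves: int

    def instance_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def assemble_result(n_points: int, stem_indices: np.ndarray,
                    leaf_indices: np.ndarray, leaf_ids: np.ndarray,
                    alignment: AlignmentResult) -> SegmentationResult:
    """Combine the stem set (label 0) and leaf instances (labels 1..n_l)."""
    stem_indices = np.asarray(stem_indices, dtype=np.int64)
    leaf_indices = np.asarray(leaf_indices, dtype=np.int64)
    if len(stem_indices) + len(leaf_indices) != n_points:
        raise ValidationError("stem and leaf index sets do not partition the cloud")
    seen = np.zeros(n_points, dtype=bool)
    seen[stem_indices] = True
    if np.any(seen[leaf_indices]):
        raise ValidationError("stem and leaf index sets overlap")
    if len(leaf_indices) != len(leaf_ids):
        raise ValidationError("leaf ids do not match leaf indices")
    labels = np.zeros(n_points, dtype=np.int64)
    labels[leaf_indices] = leaf_ids
    n_leaves = int(leaf_ids.max()) if len(leaf_ids) else 0
    return SegmentationResult(labels, alignment, n_leaves)
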