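"""Minkowski distance field of a cloud relative to a base point.

The field value of a point is its Euclidean distance to the base point raised
to an exponent alpha >= 1. Exponentiation preserves the ordering of the values;
alpha only changes the contrast seen by the level-ratio test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import PointCloud

__all__ = ["ScalarField", "centroid_base_point", "minkowski_field"]


@dataclass
class ScalarField:
    values: np.ndarray          # one positive real per cloud point
    base_point: np.ndarray      # (3,)
    alpha: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


def centroid_base_point(cloud: PointCloud, perturbation: float | None = None,
                        seed: int = 0) -> np.ndarray:
    """Arithmetic mean of the cloud, nudged off any exactly coincident point.

    The collision test is exact float equality; on collision a uniform random
    offset of magnitude <= ``perturbation`` (default 1e-6 x bbox diagonal) is
    drawn from a fixed-seed RNG until the base no longer equals any point.
    """
    base = cloud.points.mean(axis=0)
    if perturbation is None:
        diag = cloud.bounding_box_diagonal()
        perturbation = 1e-6 * (diag if diag > 0 else 1.0)
    rng = np.random.default_rng(seed)
    while np.any(np.all(cloud.points == base, axis=1)):
        offset = rng.uniform(-1.0, 1.0, size=3)
        norm = np.linalg.norm(offset)
        if norm == 0:
            continue
        base = cloud.points.mean(axis=0) + offset / norm * perturbation * rng.uniform(0.5, 1.0)
    return base


def minkowski_field(cloud: PointCloud, base: np.ndarray,
                    alpha: float) -> ScalarField:
    """values[i] = ||p_i - base||_2 ** alpha, requiring base not in the cloud."""
    if alpha < 1.0:
        raise ValidationError(f"alpha must be >= 1.0, got {alpha}")
    base = np.asarray(base, dtype=np.float64).reshape(3)
    if np.any(np.all(cloud.points == base, axis=1)):
        raise ValidationError(
            "base point coincides with a cloud point; perturb it "
            "(see centroid_base_point)"
        )
    dist = np.linalg.norm(cloud.points - base, axis=1)
    return ScalarField(dist ** alpha, base, float(alpha))
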