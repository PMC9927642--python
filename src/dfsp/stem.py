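"""Stem extraction: stem-base identification, plant alignment, and region growing.

The stem-base cluster core is the one whose members sit on the most cylindrical
surface, measured by the eigenvalue feature ``lambda3 * (lambda1 - lambda2) /
lambda1`` averaged over the core (leaf patches are planar, so lambda3 ~ 0;
the stem is linear with non-negligible thickness). The plant is then aligned so
the growth direction — the median of unit vectors from the stem core to the
leaf cores — becomes +z with the stem base at the origin, and the stem is grown
from the origin by median normalized-vector growth (MNVG) until the seed rises
above a fraction mu of the plant height.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import skew

from .errors import ValidationError
from .field import centroid_base_point
from .io import PointCloud
from .quickshiftpp import ClusterCore, QspConfig, dfsp_segment

__all__ = [
    "StemFeatureConfig",
    "MnvgConfig",
    "StemConfig",
    "AlignmentResult",
    "local_pca_eigenvalues",
    "core_stem_feature",
    "identify_stem_core",
    "estimate_growth_direction",
    "align_plant",
    "mnvg_grow_stem",
    "segment_stem",
]


@dataclass
class StemFeatureConfig:
    k_f: int = 64

    def __post_init__(self) -> None:
        if self.k_f < 3:
            raise ValidationError("k_f must be >= 3")


@dataclass
class MnvgConfig:
    mu: float = 0.30
    r: Optional[float] = None   # None -> max pairwise distance in the stem core
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError("mu must be in [0, 1]")
        if self.r is not None and self.r <= 0:
            raise ValidationError("r must be > 0")


@dataclass
class StemConfig:
    """Bundle of every parameter the stem stage consumes."""

    alpha1: float = 5.0
    qsp: QspConfig = dc_field(default_factory=lambda: QspConfig(k=32, beta=0.85))
    feature: StemFeatureConfig = dc_field(default_factory=StemFeatureConfig)
    mnvg: MnvgConfig = dc_field(default_factory=MnvgConfig)
    base_seed: int = 0  # RNG seed for the base-point collision perturbation


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 3x3 orthonormal; aligned = R @ p + translation
    translation: np.ndarray       # 3-vector
    growth_direction: np.ndarray  # unit vector in ORIGINAL coordinates
    stem_base: np.ndarray         # p_s in original coordinates
    h: float                      # max z of the aligned cloud

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse_transform(self, points: np.ndarray) -> np.ndarray:
        return (points - self.translation) @ self.rotation


def local_pca_eigenvalues(cloud: PointCloud, index: int, k_f: int,
                          tree: Optional[cKDTree] = None) -> Tuple[float, float, float]:
    """Eigenvalues (descending) of the covariance of the point's k_f-neighborhood.

    The neighborhood includes the query point itself. A fully coincident
    neighborhood yields (0, 0, 0).
    """
    if k_f > cloud.n:
        raise ValidationError(f"k_f={k_f} exceeds cloud size {cloud.n}")
    if tree is None:
        tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points[index], k=k_f)
    nb = cloud.points[np.atleast_1d(idx)]
    centered = nb - nb.mean(axis=0)
    if np.allclose(centered, 0):
        return (0.0, 0.0, 0.0)
    cov = centered.T @ centered / max(nb.shape[0] - 1, 1)
    ev = np.linalg.eigvalsh(cov)[::-1]
    ev = np.clip(ev, 0.0, None)
    return (float(ev[0]), float(ev[1]), float(ev[2]))


def core_stem_feature(cloud: PointCloud, core: ClusterCore,
                      cfg: StemFeatureConfig = StemFeatureConfig(),
                      tree: Optional[cKDTree] = None) -> float:
    """Mean of lambda3*(lambda1-lambda2)/lambda1 over core members.

    Neighborhoods are drawn from the full cloud, not only core members; a
    member with lambda1 == 0 contributes 0.
    """
    if core.size == 0:
        raise ValidationError("empty cluster core")
    if tree is None:
        tree = cKDTree(cloud.points)
    k_f = min(cfg.k_f, cloud.n)
    total = 0.0
    for i in core.member_indices:
        l1, l2, l3 = local_pca_eigenvalues(cloud, int(i), k_f, tree=tree)
        if l1 > 0:
            total += l3 * (l1 - l2) / l1
    return total / core.size


def identify_stem_core(cloud: PointCloud, cores: List[ClusterCore],
                       cfg: StemFeatureConfig = StemFeatureConfig(),
                       ) -> Tuple[ClusterCore, List[ClusterCore]]:
    """Pick the core with the largest stem feature; ties by lower core index."""
    if len(cores) < 2:
        raise ValidationError("cannot separate stem from leaves: need >= 2 cores")
    tree = cKDTree(cloud.points)
    feats = [core_stem_feature(cloud, c, cfg, tree=tree) for c in cores]
    best = int(np.argmax(feats))  # first occurrence wins ties
    leaf_cores = [c for i, c in enumerate(cores) if i != best]
    return cores[best], leaf_cores


def estimate_growth_direction(stem_core: ClusterCore,
                              leaf_cores: List[ClusterCore]) -> np.ndarray:
    """Component-wise median of unit vectors stem-median -> leaf-medians, renormalized."""
    if not leaf_cores:
        raise ValidationError("need at least one leaf core")
    ps = stem_core.median_point
    units = []
    for lc in leaf_cores:
        v = lc.median_point - ps
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        units.append(v / nrm)
    if not units:
        raise ValidationError("degenerate symmetric configuration")
    med = np.median(np.array(units), axis=0)
    nrm = np.linalg.norm(med)
    if nrm < 1e-6:
        raise ValidationError("degenerate symmetric configuration")
    return med / nrm


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``direction`` to (0, 0, 1)."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(d, z))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    axis = axis / s
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def align_plant(cloud: PointCloud, stem_core: ClusterCore,
                direction: np.ndarray) -> Tuple[PointCloud, AlignmentResult]:
    """Canonical pose: stem-core median at the origin, growth direction -> +z,
    horizontal principal axes -> x/y (x sign fixed so skewness(x) >= 0)."""
    ps = stem_core.median_point.copy()
    r1 = _rotation_to_z(np.asarray(direction, dtype=np.float64))
    pts1 = (cloud.points - ps) @ r1.T
    # in-plane PCA: align first/second principal components with x/y
    xy = pts1[:, :2] - pts1[:, :2].mean(axis=0)
    cov = xy.T @ xy / max(xy.shape[0] - 1, 1)
    w, v = np.linalg.eigh(cov)
    pc1 = v[:, int(np.argmax(w))]
    theta = np.arctan2(pc1[1], pc1[0])
    ct, st = np.cos(-theta), np.sin(-theta)
    rz = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
    pts2 = pts1 @ rz.T
    if skew(pts2[:, 0]) < 0:
        flip = np.diag([-1.0, -1.0, 1.0])  # proper 180 deg about z
        rz = flip @ rz
        pts2 = pts1 @ rz.T
    rotation = rz @ r1
    translation = -rotation @ ps
    aligned = PointCloud(pts2, cloud.labels.copy() if cloud.labels is not None else None)
    d = np.asarray(direction, dtype=np.float64)
    result = AlignmentResult(
        rotation=rotation,
        translation=translation,
        growth_direction=d / np.linalg.norm(d),
        stem_base=ps,
        h=float(pts2[:, 2].max()),
    )
    return aligned, result


def core_diameter(core: ClusterCore, points: np.ndarray) -> float:
    """Euclidean distance between the farthest two points of a core."""
    pts = points[core.member_indices]
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 2000:  # diameter is attained on the convex hull; subsample guard
        rng = np.random.default_rng(0)
        pts = pts[rng.choice(pts.shape[0], 2000, replace=False)]
    return float(pdist(pts).max())


def mnvg_grow_stem(aligned: PointCloud, cfg: MnvgConfig,
                   trace: Optional[list] = None) -> np.ndarray:
    """Median normalized-vector growth from the origin along the stem.

    Each iteration adds every point within radius r of the seed to the stem
    set, advances the seed by r along the (previous-direction-smoothed)
    component-wise median of unit vectors to those points, and stops as soon as
    the *next* seed would rise above mu * h (its sphere is not added).
    """
    if cfg.r is None:
        raise ValidationError("MNVG radius r is not set")
    pts = aligned.points
    h = float(pts[:, 2].max())
    if h <= 0:
        raise ValidationError("aligned cloud has no extent above the origin")
    tree = cKDTree(pts)
    in_stem = np.zeros(aligned.n, dtype=bool)
    s = np.zeros(3)
    v_prev = np.zeros(3)
    for j in range(cfg.max_iter):
        idx = np.array(tree.query_ball_point(s, cfg.r), dtype=np.int64)
        if idx.size == 0:
            if j == 0:
                raise ValidationError("seed not on plant: no points within r of origin")
            break  # gap in the cloud: normal termination
        in_stem[idx] = True
        vec = pts[idx] - s
        norms = np.linalg.norm(vec, axis=1)
        good = norms > 1e-12
        if not np.any(good):
            break
        units = vec[good] / norms[good, None]
        v = np.median(units, axis=0)
        v = v + v_prev
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v = v / nv
        s_next = s + cfg.r * v
        if trace is not None:
            trace.append((s.copy(), v.copy(), s_next.copy()))
        if s_next[2] > cfg.mu * h:
            break
        s = s_next
        v_prev = v
    return np.flatnonzero(in_stem)


def segment_stem(cloud: PointCloud, cfg: StemConfig = StemConfig(),
                 ) -> Tuple[np.ndarray, np.ndarray, AlignmentResult, List[ClusterCore]]:
    """Full stem stage: organ-end cores -> stem core -> alignment -> MNVG.

    Returns (stem indices, leaf-point indices, alignment, leaf cores); indices
    refer to the input cloud.
    """
    base = centroid_base_point(cloud, seed=cfg.base_seed)
    result = dfsp_segment(cloud, base, cfg.alpha1, cfg.qsp, cores_only=True)
    if len(result.cores) < 2:
        raise ValidationError(
            f"found {len(result.cores)} cluster core(s); cannot separate stem from leaves"
        )
    stem_core, leaf_cores = identify_stem_core(cloud, result.cores, cfg.feature)
    direction = estimate_growth_direction(stem_core, leaf_cores)
    aligned, alignment = align_plant(cloud, stem_core, direction)
    r = cfg.mnvg.r
    if r is None:
        r = core_diameter(stem_core, cloud.points)
        if r <= 0:
            raise ValidationError("stem core has zero diameter")
    mnvg = MnvgConfig(mu=cfg.mnvg.mu, r=r, max_iter=cfg.mnvg.max_iter)
    stem_idx = mnvg_grow_stem(aligned, mnvg)
    mask = np.zeros(cloud.n, dtype=bool)
    mask[stem_idx] = True
    leaf_idx = np.flatnonzero(~mask)
    return stem_idx, leaf_idx, alignment, leaf_cores
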