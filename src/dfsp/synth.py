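"""Labeled synthetic maize-shoot point clouds.

Procedural geometry with the structure the distance-field pipeline assumes:
a short, slightly curved stem (the stem of a pre-jointing maize plant is
roughly a third of the plant height), leaves on arching midribs in alternate
phyllotaxy whose tips disperse in space, and optionally tightly wrapped new
leaves hugging the whorl above the stem top. Sensor imperfections are modelled
as isotropic Gaussian jitter plus dropout in spherical patches. No botanical
fidelity is claimed beyond what the segmentation premise needs: every organ's
terminal region is the organ's farthest area from the plant centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .io import PointCloud

__all__ = ["PlantSpec", "PlantTruth", "generate_plant", "generate_plant_with_truth",
           "generate_suite", "generate_wrapped_apex"]


# Shape constants of the procedural geometry (fractions of stem length H or of
# leaf length L). Chosen so that, at default noise, the distance-field premise
# holds and the published parameters (beta=0.85, mu=0.30) land where they do on
# the paper's seedling data: stem ~1/3 of plant height, leaves exiting the
# near-axis region quickly.
_SHAPE = {
    "curve_amp": 0.04,        # stem axis lateral drift, x H
    # the lowest attachment must clear the stem-bottom upper-level-set region
    # (distance >= (1-beta)^(1/alpha) of the bottom's), or no stem core forms
    "attach_lo": 0.45,        # lowest / highest leaf attachment, x H
    "attach_hi": 0.95,
    "leaf_len_lo": 2.1,       # leaf length profile endpoints, x H
    "leaf_len_hi": 3.0,
    "eta_lo": 0.30,           # vertical tip gain, x L (lowest -> highest rank)
    "eta_hi": 0.62,
    "rho_lo": 1.00,           # radial tip reach, x L (lowest -> highest rank)
    "rho_hi": 0.55,
    "ctrl_radial": 0.60,      # midrib control point, x rho / x eta
    "ctrl_vertical": 0.35,
    "leaf_width": 0.11,       # max blade width, x L
    "wrap_attach_lo": 0.80,   # wrapped-leaf attachment, x H
    "wrap_radius_pad": 2.5,   # first wrap sits this far off the stem surface
    "wrap_radius_step": 1.5,
    "wrap_top_lo": 0.72,      # wrapped tip height, x plant height
    "wrap_top_step": 0.09,
    "wrap_span_deg": 100.0,
}


@dataclass
class PlantSpec:
    n_leaves: int = 6
    height: float = 55.0          # stem length; the plant is ~3x taller
    stem_radius: float = 3.0
    leaf_length_profile: Optional[Sequence[float]] = None
    phyllotaxy_jitter_deg: float = 12.0
    wrap_fraction: float = 0.2
    points_total: int = 6000
    noise_sd: float = 0.2
    dropout: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValidationError("n_leaves must be >= 1")
        if self.height <= 0 or self.stem_radius <= 0:
            raise ValidationError("all lengths must be > 0")
        if not (0.0 <= self.wrap_fraction < 1.0):
            raise ValidationError("wrap_fraction must be in [0, 1)")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.leaf_length_profile is not None:
            prof = np.asarray(self.leaf_length_profile, dtype=float)
            if np.any(prof <= 0):
                raise ValidationError("leaf lengths must be > 0")
            if np.any(prof > 10 * self.height):
                raise ValidationError("impossible geometry: leaf longer than 10x height")

    @property
    def n_wrapped(self) -> int:
        n = int(round(self.wrap_fraction * self.n_leaves))
        return min(n, self.n_leaves - 1) if self.n_leaves > 1 else 0


@dataclass
class PlantTruth:
    """Generator-side ground truth used by tests and diagnostics."""

    organ_ends: Dict[int, np.ndarray]   # label -> coordinates of the organ's end
    plant_height: float                 # max z of the noise-free surfaces
    stem_axis: np.ndarray               # (m, 3) polyline of the stem axis
    wrapped_labels: List[int]           # labels generated as wrapped new leaves


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bezier(p0, c, p2, u):
    u = u[:, None]
    return (1 - u) ** 2 * p0 + 2 * u * (1 - u) * c + u ** 2 * p2


def generate_plant_with_truth(spec: PlantSpec) -> Tuple[PointCloud, PlantTruth]:
    rng = np.random.default_rng(spec.seed)
    H = spec.height
    r_stem = spec.stem_radius

    S = _SHAPE

    # stem axis: vertical with a slight quadratic lateral drift
    curve_az = rng.uniform(0, 2 * np.pi)
    curve_dir = np.array([np.cos(curve_az), np.sin(curve_az), 0.0])
    curve_amp = S["curve_amp"] * H

    def axis(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return curve_amp * (t ** 2)[:, None] * curve_dir + \
            np.column_stack([np.zeros_like(t), np.zeros_like(t), t * H])

    n_wrap = spec.n_wrapped
    n_norm = spec.n_leaves - n_wrap

    # --- leaf geometry ---------------------------------------------------
    az0 = rng.uniform(0, 2 * np.pi)
    jitter = np.deg2rad(spec.phyllotaxy_jitter_deg)

    normal_leaves = []  # (attach_t, azimuth, L, eta, rho)
    for i in range(n_norm):
        g = i / max(n_norm - 1, 1)
        if spec.leaf_length_profile is not None and i < len(spec.leaf_length_profile):
            L = float(spec.leaf_length_profile[i])
        else:
            L = H * (S["leaf_len_lo"] + (S["leaf_len_hi"] - S["leaf_len_lo"]) * g)
        if L > 10 * H:
            raise ValidationError("impossible geometry: leaf longer than 10x height")
        attach_t = S["attach_lo"] + (S["attach_hi"] - S["attach_lo"]) * g
        azimuth = az0 + np.pi * i + rng.uniform(-jitter, jitter)
        eta = L * (S["eta_lo"] + (S["eta_hi"] - S["eta_lo"]) * g)  # vertical tip gain
        rho = L * (S["rho_lo"] + (S["rho_hi"] - S["rho_lo"]) * g)  # radial tip reach
        normal_leaves.append((attach_t, azimuth, L, eta, rho))

    plant_height_est = max(
        [H] + [a * H + e for a, _, _, e, _ in normal_leaves]
    )

    wrapped_leaves = []  # (attach_t, azimuth, radius, length, span)
    for j in range(n_wrap):
        attach_t = S["wrap_attach_lo"] + 0.12 * (
            j / max(n_wrap - 1, 1) if n_wrap > 1 else 0.0)
        azimuth = az0 + np.pi * (n_norm + j) + rng.uniform(-jitter, jitter)
        radius = r_stem + S["wrap_radius_pad"] + S["wrap_radius_step"] * j
        top = (S["wrap_top_lo"] + S["wrap_top_step"] * j) * plant_height_est
        length = max(top - attach_t * H, 0.4 * H)
        span = np.deg2rad(S["wrap_span_deg"])
        wrapped_leaves.append((attach_t, azimuth, radius, length, span))

    # --- point budget proportional to surface area -----------------------
    areas = {0: 2 * np.pi * r_stem * H}
    for li, (_, _, L, _, _) in enumerate(normal_leaves, start=1):
        areas[li] = 0.085 * L ** 2
    for wj, (_, _, radius, length, span) in enumerate(wrapped_leaves,
                                                      start=1 + n_norm):
        areas[wj] = 0.6 * span * radius * length
    total_area = sum(areas.values())
    counts = {lab: max(40, int(round(spec.points_total * a / total_area)))
              for lab, a in areas.items()}

    pts_list, lab_list = [], []
    organ_ends: Dict[int, np.ndarray] = {}

    # stem surface
    ns = counts[0]
    t = rng.uniform(0, 1, ns)
    theta = rng.uniform(0, 2 * np.pi, ns)
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(ns)])
    pts_list.append(axis(t) + r_stem * radial)
    lab_list.append(np.zeros(ns, dtype=np.int64))
    organ_ends[0] = axis(np.array([0.0]))[0]

    # expanded leaves: ruled surface over an arching quadratic midrib
    for li, (attach_t, azimuth, L, eta, rho) in enumerate(normal_leaves, start=1):
        radial_dir = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
        lateral = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
        p0 = axis(np.array([attach_t]))[0] + r_stem * radial_dir
        tip = p0 + rho * radial_dir + eta * np.array([0, 0, 1.0])
        ctrl = p0 + S["ctrl_radial"] * rho * radial_dir \
            + S["ctrl_vertical"] * eta * np.array([0, 0, 1.0])
        nl = counts[li]
        # mostly area-uniform along the midrib (density ~ blade width), with a
        # uniform floor so the tapering tip and collar stay represented
        u_grid = np.linspace(0, 1, 512)
        w_grid = np.sin(np.pi * u_grid) ** 0.6
        cdf = np.cumsum(w_grid)
        cdf /= cdf[-1]
        u_area = np.interp(rng.uniform(0, 1, nl), cdf, u_grid)
        u_unif = rng.uniform(0, 1, nl)
        u = np.where(rng.uniform(0, 1, nl) < 0.8, u_area, u_unif)
        s = rng.uniform(-0.5, 0.5, nl)
        w = S["leaf_width"] * L * np.sin(np.pi * u) ** 0.6
        pts = _bezier(p0, ctrl, tip, u) + (s * w)[:, None] * lateral
        pts_list.append(pts)
        lab_list.append(np.full(nl, li, dtype=np.int64))
        organ_ends[li] = tip

    # wrapped new leaves: tapering partial shells around the whorl
    wrapped_labels = []
    for wj, (attach_t, azimuth, radius, length, span) in enumerate(
            wrapped_leaves, start=1 + n_norm):
        wrapped_labels.append(wj)
        nw = counts[wj]
        base = axis(np.array([attach_t]))[0]
        top_axis = axis(np.array([1.0]))[0]
        axis_xy = np.where(np.array([True, True, False]),
                           top_axis - base, 0.0)  # keep shell centred near whorl
        u = rng.uniform(0, 1, nw)
        phi = azimuth + rng.uniform(-0.5, 0.5, nw) * span * (1 - 0.8 * u)
        # sheath collar: the shell grows out of the stem surface over the
        # first 15% of its length, keeping the whorl graph-connected
        r_u = r_stem + (radius - r_stem) * np.minimum(1.0, u / 0.15)
        x = base[0] + u * axis_xy[0] + r_u * np.cos(phi)
        y = base[1] + u * axis_xy[1] + r_u * np.sin(phi)
        z = base[2] + u * length
        pts_list.append(np.column_stack([x, y, z]))
        lab_list.append(np.full(nw, wj, dtype=np.int64))
        organ_ends[wj] = np.array([
            base[0] + axis_xy[0] + radius * np.cos(azimuth),
            base[1] + axis_xy[1] + radius * np.sin(azimuth),
            base[2] + length,
        ])

    points = np.vstack(pts_list)
    labels = np.concatenate(lab_list)
    plant_height = float(points[:, 2].max())

    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd, points.shape)

    # dropout in spherical patches (never starving an organ below 20 points)
    if spec.dropout > 0:
        keep = np.ones(points.shape[0], dtype=bool)
        target = int(spec.dropout * points.shape[0])
        removed = 0
        patch_r = 0.025 * plant_height
        for _ in range(400):
            if removed >= target:
                break
            center = points[rng.integers(0, points.shape[0])]
            hit = keep & (np.linalg.norm(points - center, axis=1) < patch_r)
            trial = keep & ~hit
            sizes = np.bincount(labels[trial], minlength=spec.n_leaves + 1)
            if np.any(sizes[np.unique(labels)] < 20):
                continue
            removed += int(hit.sum())
            keep = trial
        points, labels = points[keep], labels[keep]

    truth = PlantTruth(
        organ_ends=organ_ends,
        plant_height=plant_height,
        stem_axis=axis(np.linspace(0, 1, 2048)),
        wrapped_labels=wrapped_labels,
    )
    return PointCloud(points, labels), truth


def generate_plant(spec: PlantSpec) -> PointCloud:
    """Deterministic labeled synthetic maize shoot (stem label 0, leaves 1..n)."""
    cloud, _ = generate_plant_with_truth(spec)
    return cloud


def generate_wrapped_apex(seed: int) -> PointCloud:
    """Hard-apex fixture: two wrapped new leaves that touch at the whorl base.

    The inner leaf is a short near-cylindrical shell; the outer one starts in
    contact with it and flares away toward a distinct, higher tip. Any single
    Euclidean distance tolerance therefore merges the pair, while tip-seeded
    distance-field clustering separates them. Labels are 1 and 2; the stem
    base (the field base point for the leaf stage) is the origin.
    """
    rng = np.random.default_rng(seed)
    pts, labs = [], []
    # (inner radius, outer radius, base z, length, azimuth, spiral, n, flare)
    specs = [(5.0, 5.0, 40.0, 40.0, 0.0, 0.0, 900, 1.0),
             (5.4, 11.0, 40.0, 90.0, 1.5, 1.6, 1800, 0.6)]
    for lab, (r0, r1, z0, length, az, spiral, n, flare) in enumerate(specs,
                                                                    start=1):
        u = rng.uniform(0, 1, n)
        span = np.deg2rad(140)
        phi = az + spiral * u + rng.uniform(-0.5, 0.5, n) * span * (1 - 0.8 * u)
        r = r0 + (r1 - r0) * u ** flare
        p = np.column_stack([r * np.cos(phi), r * np.sin(phi), z0 + u * length])
        pts.append(p + rng.normal(0, 0.1, (n, 3)))
        labs.append(np.full(n, lab))
    return PointCloud(np.vstack(pts), np.concatenate(labs))


def generate_suite(seeds: Sequence[int], leaf_counts: Sequence[int],
                   **overrides) -> List[Tuple[PointCloud, PlantSpec]]:
    """Factorial battery: one plant per (leaf count, seed) pair."""
    if not seeds or not leaf_counts:
        raise ValidationError("seeds and leaf_counts must be non-empty")
    out = []
    for n_leaves in leaf_counts:
        for seed in seeds:
            spec = PlantSpec(n_leaves=int(n_leaves), seed=int(seed), **overrides)
            out.append((generate_plant(spec), spec))
    return out
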