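"""Mode-seeking clustering on an arbitrary per-point scalar field.

Two stages: a persistence sweep over the k-NN graph recovers *cluster cores*
(connected regions of the field's upper level sets that stay separate until
their level drops below ``(1 - beta) * peak``), then a hill-climbing pass
assigns every remaining point to a core along ascending-field nearest-neighbor
links. The field is arbitrary — here it is the Minkowski distance field rather
than the k-NN density estimate the clustering literature uses, which is what
turns organ *ends* into cluster cores.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .field import ScalarField, minkowski_field
from .io import PointCloud

__all__ = [
    "KnnGraph",
    "ClusterCore",
    "QspConfig",
    "DfspResult",
    "build_knn_graph",
    "find_cluster_cores",
    "hill_climb_assign",
    "dfsp_segment",
]

log = logging.getLogger(__name__)


@dataclass
class KnnGraph:
    """Exact Euclidean k-NN lists plus the symmetrized (union) edge set."""

    k: int
    neighbors: np.ndarray   # (n, k) int, sorted ascending by (distance, index)
    distances: np.ndarray   # (n, k) float, matching
    points: np.ndarray      # (n, 3) coordinates the graph was built from

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def undirected_edges(self) -> np.ndarray:
        """Unique {i, j} pairs where j in kNN(i) or i in kNN(j), as (m, 2) with i<j."""
        n, k = self.neighbors.shape
        src = np.repeat(np.arange(n), k)
        dst = self.neighbors.ravel()
        lo = np.minimum(src, dst)
        hi = np.maximum(src, dst)
        pairs = np.unique(np.column_stack([lo, hi]), axis=0)
        return pairs

    def adjacency(self) -> List[np.ndarray]:
        """Per-point undirected neighbor index lists (union symmetrization)."""
        edges = self.undirected_edges()
        adj: List[list] = [[] for _ in range(self.n)]
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        return [np.array(sorted(x), dtype=np.int64) for x in adj]


@dataclass
class ClusterCore:
    """A locally-high-field region: the persistence core of one mode."""

    member_indices: np.ndarray
    peak_index: int
    peak_value: float
    median_point: np.ndarray

    @property
    def size(self) -> int:
        return self.member_indices.shape[0]


@dataclass
class QspConfig:
    k: int
    beta: float
    min_core_size: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValidationError(f"beta must be in (0, 1), got {self.beta}")
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")


def build_knn_graph(cloud: PointCloud, k: int) -> KnnGraph:
    """Exact Euclidean k-NN, ties broken by lower index; k clamped to n-1."""
    n = cloud.n
    if n < 2:
        raise ValidationError("k-NN graph needs at least 2 points")
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k >= n:
        log.warning("k=%d >= n=%d; clamping to %d", k, n, n - 1)
        k = n - 1
    pts = cloud.points
    tree = cKDTree(pts)
    q = min(k + 2, n)
    dist, idx = tree.query(pts, k=q)
    neighbors = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=np.float64)
    # fast path assumes self sits in column 0 and no exact distance ties
    self_first = idx[:, 0] == np.arange(n)
    internal_tie = np.any(dist[:, 1:] == dist[:, :-1], axis=1)
    boundary_tie = (dist[:, -1] == dist[:, -2]) if q == k + 2 else np.zeros(n, bool)
    needs_repair = ~self_first | internal_tie | boundary_tie
    ok = ~needs_repair
    neighbors[ok] = idx[ok, 1:k + 1]
    distances[ok] = dist[ok, 1:k + 1]
    for i in np.flatnonzero(needs_repair):
        d = np.linalg.norm(pts - pts[i], axis=1)
        order = np.lexsort((np.arange(n), d))
        order = order[order != i][:k]
        neighbors[i] = order
        distances[i] = d[order]
    return KnnGraph(k, neighbors, distances, pts)


def _median_point(points: np.ndarray) -> np.ndarray:
    return np.median(points, axis=0)


def find_cluster_cores(graph: KnnGraph, field: ScalarField,
                       cfg: QspConfig) -> List[ClusterCore]:
    """Persistence sweep in decreasing field order over the union k-NN graph.

    A component is born at its peak (the first of its points processed). When
    the sweep level first drops below ``(1 - beta) * peak`` the component's
    current membership is frozen as its core. A component that merges into a
    higher-peak component after being frozen contributes its frozen core; one
    that merges before freezing simply dies. Surviving roots contribute their
    frozen core, or their whole membership if the level never reached their
    threshold (e.g. a constant field). Cores smaller than ``min_core_size``
    are discarded; their points are left to the hill-climbing stage.
    """
    values = field.values
    n = graph.n
    if n == 0 or values.shape[0] != n:
        raise ValidationError("field length does not match graph size")
    adj = graph.adjacency()
    order = np.lexsort((np.arange(n), -values))  # decreasing value, ties by index

    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    peak_value = {}    # root -> peak field value
    peak_index = {}    # root -> peak point index
    members = {}       # root -> list of member points
    frozen = {}        # root -> frozen core membership (list) or None
    finalized: List[tuple] = []  # (frozen members, peak_index, peak_value)

    heap: list = []    # (-threshold, peak_index) ; peak_index identifies the component
    processed = np.zeros(n, dtype=bool)
    one_minus_beta = 1.0 - cfg.beta

    for i in order:
        lam = values[i]
        # freeze every live component whose (1-beta)*peak exceeds the level
        while heap and -heap[0][0] > lam:
            _, pk = heapq.heappop(heap)
            r = find(pk)
            if peak_index.get(r) == pk and frozen.get(r) is None:
                frozen[r] = list(members[r])
        # birth of i as a singleton component
        parent[i] = i
        peak_value[i] = lam
        peak_index[i] = i
        members[i] = [i]
        frozen[i] = None
        heapq.heappush(heap, (-one_minus_beta * lam, i))
        processed[i] = True
        for j in adj[i]:
            if not processed[j]:
                continue
            ra, rb = find(i), find(j)
            if ra == rb:
                continue
            # winner = globally higher peak, ties by lower peak index
            if (peak_value[ra], -peak_index[ra]) >= (peak_value[rb], -peak_index[rb]):
                win, lose = ra, rb
            else:
                win, lose = rb, ra
            if frozen[lose] is not None:
                finalized.append((frozen[lose], peak_index[lose], peak_value[lose]))
            parent[lose] = win
            members[win].extend(members[lose])
            for d in (peak_value, peak_index, members, frozen):
                del d[lose]

    roots = {find(i) for i in range(n)}
    for r in roots:
        core = frozen[r] if frozen[r] is not None else members[r]
        finalized.append((core, peak_index[r], peak_value[r]))

    cores = []
    for mem, pk, pv in finalized:
        if len(mem) < cfg.min_core_size:
            continue
        mi = np.array(sorted(mem), dtype=np.int64)
        cores.append(ClusterCore(mi, int(pk), float(pv),
                                 _median_point(graph.points[mi])))
    cores.sort(key=lambda c: (-c.peak_value, c.peak_index))
    return cores


def hill_climb_assign(graph: KnnGraph, field: ScalarField,
                      cores: List[ClusterCore]) -> np.ndarray:
    """Assign every point a core id by following ascending-field k-NN links.

    Each non-core point links to the nearest neighbor in its own k-NN list with
    a strictly greater field value; chains end in a core member (id inherited)
    or a local argmax, in which case the chain attaches to the core of the
    terminus's nearest core member.
    """
    if not cores:
        raise ValidationError("hill climbing needs at least one core")
    n = graph.n
    values = field.values
    assign = np.full(n, -1, dtype=np.int64)
    for cid, core in enumerate(cores):
        assign[core.member_indices] = cid

    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if assign[i] >= 0:
            continue
        row = graph.neighbors[i]
        higher = values[row] > values[i]
        if np.any(higher):
            parent[i] = row[int(np.argmax(higher))]  # first hit in ascending order

    core_points = np.concatenate([c.member_indices for c in cores])
    core_ids = np.concatenate([
        np.full(c.size, cid, dtype=np.int64) for cid, c in enumerate(cores)
    ])
    core_tree = cKDTree(graph.points[core_points])

    def resolve(i: int) -> int:
        chain = []
        while assign[i] < 0:
            chain.append(i)
            p = parent[i]
            if p < 0:
                # orphan terminus: attach to the core of the nearest core member
                _, j = core_tree.query(graph.points[i], k=1)
                cid = int(core_ids[j])
                break
            i = p
        else:
            cid = int(assign[i])
        for c in chain:
            assign[c] = cid
        return cid

    for i in range(n):
        if assign[i] < 0:
            resolve(i)
    return assign


@dataclass
class DfspResult:
    """Artifacts of one distance-field clustering pass."""

    field: ScalarField
    graph: KnnGraph
    cores: List[ClusterCore]
    labels: Optional[np.ndarray] = None  # per-point core id; None if cores_only


def dfsp_segment(cloud: PointCloud, base: np.ndarray, alpha: float,
                 cfg: QspConfig, cores_only: bool = False) -> DfspResult:
    """Minkowski field -> k-NN graph -> cores (-> hill-climbing assignment)."""
    fld = minkowski_field(cloud, base, alpha)
    graph = build_knn_graph(cloud, cfg.k)
    cores = find_cluster_cores(graph, fld, cfg)
    labels = None
    if not cores_only:
        labels = hill_climb_assign(graph, fld, cores)
    return DfspResult(fld, graph, cores, labels)
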