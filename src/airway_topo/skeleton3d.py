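"""Tri-axial 3D skeleton computation and minimum-spanning-tree connection.

The 3D curve skeleton is built the classical way for tubular structures:
every 2D slice perpendicular to each of the three axes is thinned to a
unit-width, 8-connected in-slice skeleton, and the three axis skeletons are
multiplied voxel-wise (logical AND).  Each axis skeleton approximates a
medial surface of the tube tree; their intersection is a sparse, usually
disconnected point cloud hugging the centerline.  Prim's minimum spanning
tree over physical Euclidean distances then reconnects the points into a
single tree.

The 2D thinning used throughout is Zhang-Suen morphological thinning
(``skimage.morphology.skeletonize``), which is topology-preserving per slice.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _skeletonize_2d

from .errors import EmptySkeletonError, EmptyVolumeError, ValidationError
from .volume_io import LabelVolume


def slice_skeletonize(volume: LabelVolume, axis: int) -> LabelVolume:
    """Thin every 2D slice perpendicular to ``axis`` independently.

    Slices with no foreground stay empty; the output shape equals the input
    shape.  Thinning is idempotent on slices that are already unit-width
    8-connected curves.
    """
    if axis not in (0, 1, 2):
        raise ValidationError(f"axis must be 0, 1 or 2, got {axis}")
    if volume.n_foreground == 0:
        raise EmptyVolumeError("cannot skeletonize an empty volume")
    moved = np.moveaxis(volume.voxels, axis, 0)
    out = np.zeros_like(moved)
    for i in range(moved.shape[0]):
        sl = moved[i]
        if sl.any():
            out[i] = _skeletonize_2d(sl)
    return LabelVolume(np.moveaxis(out, 0, axis), spacing=volume.spacing, origin=volume.origin)


@dataclass
class SkeletonPoints:
    """A sparse cloud of skeleton voxels, sorted lexicographically by index."""

    points: np.ndarray  # (n, 3) int
    parent_volume_shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 3)
        order = np.lexsort((self.points[:, 2], self.points[:, 1], self.points[:, 0]))
        self.points = self.points[order]
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        shape = np.asarray(self.parent_volume_shape)
        if len(self.points) and (
            (self.points < 0).any() or (self.points >= shape[None, :]).any()
        ):
            raise ValidationError("skeleton point outside parent volume bounds")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def physical(self) -> np.ndarray:
        """(n, 3) physical coordinates of the points."""
        return self.origin + self.points * self.spacing


def combine_axis_skeletons(
    sk_x: LabelVolume, sk_y: LabelVolume, sk_z: LabelVolume
) -> SkeletonPoints:
    """Voxel-wise product (logical AND) of the three axis skeletons."""
    if not (sk_x.shape == sk_y.shape == sk_z.shape):
        raise ValidationError(
            f"axis skeleton shapes differ: {sk_x.shape}, {sk_y.shape}, {sk_z.shape}"
        )
    if not (
        np.array_equal(sk_x.spacing, sk_y.spacing)
        and np.array_equal(sk_x.spacing, sk_z.spacing)
    ):
        raise ValidationError("axis skeleton spacings differ")
    mask = sk_x.voxels & sk_y.voxels & sk_z.voxels
    if not mask.any():
        raise EmptySkeletonError(
            "the three axis skeletons have empty intersection; segmentation unusable"
        )
    return SkeletonPoints(
        np.argwhere(mask), sk_x.shape, spacing=sk_x.spacing, origin=sk_x.origin
    )


def triaxial_skeleton(volume: LabelVolume) -> SkeletonPoints:
    """Convenience: per-axis slice thinning along x, y, z, then the AND."""
    return combine_axis_skeletons(
        slice_skeletonize(volume, 0),
        slice_skeletonize(volume, 1),
        slice_skeletonize(volume, 2),
    )


@dataclass
class SkeletonTree:
    """A connected acyclic graph over skeleton voxels.

    Nodes are row indices into ``points`` (lexicographically sorted, so the
    node-id order is the voxel-index order — tie-breaks on node id are
    tie-breaks on the lexicographically smallest voxel).  Edge weights are
    physical Euclidean distances between voxel centers.
    """

    points: np.ndarray  # (n, 3) int, lexicographically sorted
    spacing: np.ndarray
    origin: np.ndarray
    edges: list  # [(i, j, w)] with i < j
    parent_volume_shape: tuple | None = None

    def __post_init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {i: {} for i in range(len(self.points))}
        for i, j, w in self.edges:
            self._adj[i][j] = w
            self._adj[j][i] = w

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def neighbors(self, node: int):
        return self._adj[node].items()

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def weight(self, u: int, v: int) -> float:
        return self._adj[u][v]

    @property
    def physical(self) -> np.ndarray:
        return self.origin + self.points * self.spacing

    @classmethod
    def build(cls, points, edges, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        """Build a tree from voxel points and index-pair edges.

        Points are sorted lexicographically and edges remapped; weights are
        recomputed as physical Euclidean distances.  Used for hand-built
        trees in analyses and tests; :func:`prim_mst` is the pipeline path.
        """
        points = np.asarray(points, dtype=np.int64).reshape(-1, 3)
        spacing = np.asarray(spacing, dtype=float)
        origin = np.asarray(origin, dtype=float)
        order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
        rank = np.empty(len(points), dtype=np.int64)
        rank[order] = np.arange(len(points))
        sorted_pts = points[order]
        phys = origin + sorted_pts * spacing
        out_edges = []
        for a, b in edges:
            i, j = int(rank[a]), int(rank[b])
            if i == j:
                raise ValidationError("self-loop edge in skeleton tree")
            w = float(np.linalg.norm(phys[i] - phys[j]))
            out_edges.append((min(i, j), max(i, j), w))
        tree = cls(sorted_pts, spacing, origin, out_edges)
        if len(out_edges) != len(points) - 1 and len(points) > 0:
            raise ValidationError("a tree on n nodes needs exactly n-1 edges")
        return tree


def _knn_candidate_edges(phys: np.ndarray, neighbor_count: int):
    n = len(phys)
    tree = cKDTree(phys)
    k = min(neighbor_count + 1, n)
    _, idx = tree.query(phys, k=k)
    idx = np.atleast_2d(idx)
    pairs = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    return pairs


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def prim_mst(points: SkeletonPoints, neighbor_count: int = 26) -> SkeletonTree:
    """Minimum spanning tree of the Euclidean graph on the skeleton points.

    Candidate edges are restricted to each point's ``neighbor_count`` nearest
    neighbours; if that candidate graph is disconnected, the closest pair of
    points between components is added iteratively until it is connected.
    Prim's algorithm then grows the tree from node 0, breaking equal-weight
    ties toward the lexicographically smallest far endpoint.
    """
    n = len(points)
    if n == 0:
        raise EmptySkeletonError("cannot build an MST on zero points")
    phys = points.physical
    if n == 1:
        return SkeletonTree(
            points.points, points.spacing, points.origin, [], points.parent_volume_shape
        )

    pairs = _knn_candidate_edges(phys, neighbor_count)
    dsu = _DSU(n)
    for i, j in pairs:
        dsu.union(i, j)

    # Bridge disconnected candidate components with globally closest pairs.
    while True:
        roots = {}
        for i in range(n):
            roots.setdefault(dsu.find(i), []).append(i)
        if len(roots) == 1:
            break
        comp = roots[min(roots, key=lambda r: min(roots[r]))]
        comp_set = set(comp)
        others = [i for i in range(n) if i not in comp_set]
        other_tree = cKDTree(phys[others])
        d, j_local = other_tree.query(phys[comp], k=1)
        # closest pair between this component and the rest; ties resolve to
        # the smallest (a, b) node pair for determinism
        best = min(
            (float(d[i]), comp[i], others[int(j_local[i])]) for i in range(len(comp))
        )
        _, a, b = best
        pairs.add((min(a, b), max(a, b)))
        dsu.union(a, b)

    adj: dict[int, list[tuple[float, int]]] = {i: [] for i in range(n)}
    for i, j in pairs:
        w = float(np.linalg.norm(phys[i] - phys[j]))
        adj[i].append((w, j))
        adj[j].append((w, i))

    visited = np.zeros(n, dtype=bool)
    visited[0] = True
    heap: list[tuple[float, int, int]] = []
    for w, j in adj[0]:
        heapq.heappush(heap, (w, j, 0))
    edges = []
    n_visited = 1
    while n_visited < n:
        w, far, near = heapq.heappop(heap)
        if visited[far]:
            continue
        visited[far] = True
        n_visited += 1
        edges.append((min(near, far), max(near, far), w))
        for w2, j in adj[far]:
            if not visited[j]:
                heapq.heappush(heap, (w2, j, far))
    return SkeletonTree(
        points.points, points.spacing, points.origin, edges, points.parent_volume_shape
    )
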