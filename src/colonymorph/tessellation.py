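"""Voronoi diagrams and Delaunay neighbour graphs of nucleus centroids.

The Voronoi diagram (VD) partitions the colony into one convex cell per
nucleus — every location belongs to its nearest centroid — and its dual,
the Delaunay triangulation (DT), connects nuclei whose Voronoi cells share
an edge.  DT adjacency is the operational definition of "nearest
neighbours" throughout the package: the per-cell neighbour count N_n and
the intercellular distance ℓ_n (mean centroid-to-centroid distance of a
cell to its Delaunay neighbours) are both read off this graph.

Two practical complications are handled here:

* **Colony boundaries.**  Voronoi cells of peripheral nuclei are unbounded;
  when a colony boundary polygon is available cells are clipped to it (else
  to the convex hull), so that clipped cell areas tile the colony exactly.
* **Spurious edges.**  Over non-convex colonies the DT bridges concavities
  with implausibly long edges.  The default prune policy drops edges longer
  than ``prune_factor`` × the median edge length (factor 3); dense,
  near-convex colonies are insensitive to this, but sparse synthetic
  stress-tests are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi
from shapely.geometry import Point, Polygon

from .io_model import DegenerateGeometryError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "VoronoiCells",
    "delaunay_graph",
    "voronoi_clipped",
    "mean_neighbor_count",
    "mean_neighbor_distance",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Delaunay adjacency over nucleus centroids.

    edges are unordered index pairs stored as an (m, 2) int array with
    i < j, lexicographically sorted — a canonical form that makes equal
    graphs array-equal.  ``hull`` lists convex-hull vertex indices, used by
    the ``interior_only`` statistics options.
    """

    positions: np.ndarray  # (n, 2) µm
    edges: np.ndarray  # (m, 2) int, i < j, lexsorted
    hull: np.ndarray  # indices of convex-hull vertices

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if e.size and np.any(e[:, 0] == e[:, 1]):
            raise ValidationError("self-edges are not allowed")
        object.__setattr__(self, "edges", e)
        n = len(self.positions)
        if n >= 3 and len(e) > 3 * n - 6:
            raise ValidationError("edge count violates planarity bound")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degree(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    @property
    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def interior_mask(self, margin: Optional[float] = None) -> np.ndarray:
        """Bulk nodes: more than ``margin`` µm inside the convex-hull
        boundary (default 1.1 × median edge length, i.e. deeper than one
        cell row).  A purely vertex-based notion would miss border nodes
        sitting in shallow concavities of jagged colony edges.
        """
        if margin is None:
            margin = 1.1 * float(np.median(self.edge_lengths)) if self.n_edges \
                else 0.0
        hull = ConvexHull(self.positions)
        normals, offsets = hull.equations[:, :2], hull.equations[:, 2]
        # signed distance to nearest facet (negative = inside)
        dist = (self.positions @ normals.T + offsets).max(axis=1)
        return dist <= -margin


@dataclass(frozen=True)
class VoronoiCells:
    """Clipped Voronoi cells, one polygon per input point (same order)."""

    polygons: list = field(default_factory=list)  # shapely Polygons
    clip_boundary: Optional[Polygon] = None

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])


def _canonical_edges(edge_set: set[tuple[int, int]]) -> np.ndarray:
    if not edge_set:
        return np.empty((0, 2), dtype=int)
    arr = np.array(sorted(edge_set), dtype=int)
    return arr


def delaunay_graph(
    points: np.ndarray,
    prune: str = "median",
    prune_factor: float = 3.0,
) -> NeighborGraph:
    """Build the Delaunay neighbour graph of a planar point set.

    Parameters
    ----------
    points : (n, 2) coordinates in µm, n ≥ 3, not all collinear, no
        duplicates.
    prune : ``"median"`` removes edges longer than ``prune_factor`` × the
        median Delaunay edge length (guards against spurious bridges across
        colony concavities); ``"none"`` keeps the full triangulation.

    Deterministic: identical input always yields the identical canonical
    edge array.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 points for a triangulation, got {len(pts)}"
        )
    _, inverse, counts = np.unique(
        pts, axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_groups = np.flatnonzero(counts > 1)
        dup_idx = sorted(
            int(i) for g in dup_groups for i in np.flatnonzero(inverse == g)
        )
        raise ValidationError(f"duplicate points at indices {dup_idx}")
    if prune not in ("median", "none"):
        raise ValueError(f"unknown prune policy {prune!r}")

    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise DegenerateGeometryError(
            "Delaunay triangulation failed (collinear or degenerate input)"
        ) from err
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points are collinear")

    edge_set: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        a, b, c = (int(v) for v in simplex)
        edge_set.add((min(a, b), max(a, b)))
        edge_set.add((min(b, c), max(b, c)))
        edge_set.add((min(a, c), max(a, c)))
    edges = _canonical_edges(edge_set)

    if prune == "median" and len(edges):
        d = pts[edges[:, 0]] - pts[edges[:, 1]]
        lengths = np.hypot(d[:, 0], d[:, 1])
        cutoff = prune_factor * np.median(lengths)
        keep = lengths <= cutoff
        if not keep.all():
            logger.info(
                "pruned %d/%d Delaunay edges longer than %.3g µm",
                (~keep).sum(), len(edges), cutoff,
            )
        edges = edges[keep]

    # hull = every node ON the convex-hull boundary, not just its vertices:
    # lattice boundary nodes collinear with hull edges must count as hull
    # for interior_only statistics to isolate true bulk nodes.
    hull_obj = ConvexHull(pts)
    normals, offsets = hull_obj.equations[:, :2], hull_obj.equations[:, 2]
    scale = float(np.ptp(pts, axis=0).max())
    on_hull = (pts @ normals.T + offsets >= -1e-9 * max(scale, 1.0)).any(axis=1)
    hull = np.flatnonzero(on_hull)
    return NeighborGraph(positions=pts, edges=edges, hull=hull)


def voronoi_clipped(points: np.ndarray, boundary: Polygon) -> VoronoiCells:
    """Voronoi cells of ``points`` clipped to a boundary polygon.

    Every point must lie strictly inside the boundary.  The clipped cells
    are pairwise disjoint (up to shared edges) and tile the boundary: their
    areas sum to the boundary area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    for i, p in enumerate(pts):
        if not boundary.contains(Point(p)):
            raise ValidationError(f"point {i} at {tuple(p)} is not strictly "
                                  "inside the boundary")

    if len(pts) == 1:
        return VoronoiCells(polygons=[Polygon(boundary.exterior)],
                            clip_boundary=boundary)

    # Four distant ghost generators make every real region finite; any
    # location inside the boundary is far closer to a real point than to a
    # ghost, so clipping is unaffected.
    minx, miny, maxx, maxy = boundary.bounds
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    span = 100.0 * max(maxx - minx, maxy - miny, 1.0)
    ghosts = np.array([
        [cx - span, cy], [cx + span, cy], [cx, cy - span], [cx, cy + span]
    ])
    vor = Voronoi(np.vstack([pts, ghosts]))

    polygons = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # cannot happen inside the ghost frame
            raise DegenerateGeometryError(f"unbounded Voronoi region for point {i}")
        cell = Polygon(vor.vertices[region]).intersection(boundary)
        polygons.append(cell)
    return VoronoiCells(polygons=polygons, clip_boundary=boundary)


def mean_neighbor_count(
    graph: NeighborGraph, interior_only: bool = False
) -> tuple[float, np.ndarray]:
    """⟨N_n⟩ and per-node Delaunay neighbour counts.

    Over all nodes ⟨N_n⟩ = 2·|edges|/n; with ``interior_only`` the average
    is restricted to non-hull nodes (lattice interiors give exactly 6).
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    deg = graph.degree
    if interior_only:
        mask = graph.interior_mask()
        if not mask.any():
            raise ValueError("no interior nodes to average over")
        return float(deg[mask].mean()), deg
    return float(2 * graph.n_edges / graph.n_nodes), deg


def mean_neighbor_distance(
    graph: NeighborGraph,
    interior_only: bool = False,
    aggregation: str = "per_node",
) -> tuple[float, np.ndarray]:
    """⟨ℓ_n⟩ and per-node mean distances to Delaunay neighbours.

    Each node's value is the mean centroid distance to its neighbours;
    ⟨ℓ_n⟩ averages these per-node values so each cell contributes equally
    (``aggregation="per_edge"`` instead averages over unique edges).
    Isolated nodes (possible after pruning) are excluded and logged.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if aggregation not in ("per_node", "per_edge"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    lengths = graph.edge_lengths
    sums = np.zeros(graph.n_nodes)
    np.add.at(sums, graph.edges[:, 0], lengths)
    np.add.at(sums, graph.edges[:, 1], lengths)
    deg = graph.degree
    per_node = np.full(graph.n_nodes, np.nan)
    connected = deg > 0
    per_node[connected] = sums[connected] / deg[connected]
    if not connected.all():
        logger.info("excluding %d isolated node(s) from <l_n>",
                    int((~connected).sum()))

    if aggregation == "per_edge":
        overall = float(lengths.mean())
    else:
        mask = connected
        if interior_only:
            mask = mask & graph.interior_mask()
        if not mask.any():
            raise ValueError("no nodes left to average over")
        overall = float(per_node[mask].mean())
    return overall, per_node
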