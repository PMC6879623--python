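"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive and self-contained: nothing here touches scipy.spatial
or the package's own geometry code, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edges by the empty-circumcircle definition.

    An edge (i, j) is Delaunay iff some triple (i, j, k) has a circumcircle
    whose interior contains no other point.  O(n^4); use only for small n.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    x, y = pts[:, 0], pts[:, 1]
    sq = x * x + y * y
    for i, j, k in combinations(range(n), 3):
        ax, ay, bx, by, cx, cy = x[i], y[i], x[j], y[j], x[k], y[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if d == 0.0:  # collinear triple: no circumcircle
            continue
        ux = (sq[i] * (by - cy) + sq[j] * (cy - ay) + sq[k] * (ay - by)) / d
        uy = (sq[i] * (cx - bx) + sq[j] * (ax - cx) + sq[k] * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        d2 = (x - ux) ** 2 + (y - uy) ** 2
        mask = np.ones(n, dtype=bool)
        mask[[i, j, k]] = False
        if np.all(d2[mask] > r2 * (1.0 - 1e-12)):
            for a, b in ((i, j), (i, k), (j, k)):
                edges.add((min(a, b), max(a, b)))
    return edges


def brute_feret(vertices: np.ndarray) -> float:
    """Maximum pairwise vertex distance over ALL vertices (no hull)."""
    v = np.asarray(vertices, dtype=float)
    best = 0.0
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            d = float(np.hypot(*(v[i] - v[j])))
            best = max(best, d)
    return best


def fan_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Polygon centroid by fan triangulation from vertex 0 (signed areas)."""
    v = np.asarray(vertices, dtype=float)
    total_a = 0.0
    cx = cy = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        tri_a = 0.5 * ((b[0] - a[0]) * (c[1] - a[1])
                       - (c[0] - a[0]) * (b[1] - a[1]))
        tx, ty = (a[0] + b[0] + c[0]) / 3.0, (a[1] + b[1] + c[1]) / 3.0
        total_a += tri_a
        cx += tri_a * tx
        cy += tri_a * ty
    return cx / total_a, cy / total_a


def brute_delta(n_nodes: int, edge_list, labels) -> float:
    """Segregation order parameter by direct edge enumeration."""
    labels = list(labels)
    n_a = sum(1 for lab in labels if lab == "A")
    n_b = n_nodes - n_a
    if n_a == 0 or n_b == 0:
        raise ValueError("both classes must be nonempty")
    n_ab = sum(1 for i, j in edge_list if labels[i] != labels[j])
    n_n = 2.0 * len(edge_list) / n_nodes
    return 1.0 - (n_nodes * n_ab) / (n_n * n_a * n_b)


def brute_mean_neighbor_distance(points: np.ndarray, edge_list) -> float:
    """Per-node mean neighbour distance, averaged over connected nodes."""
    pts = np.asarray(points, dtype=float)
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(pts))}
    for i, j in edge_list:
        nbrs[i].append(j)
        nbrs[j].append(i)
    per_node = [
        sum(float(np.hypot(*(pts[i] - pts[j]))) for j in js) / len(js)
        for i, js in nbrs.items() if js
    ]
    return sum(per_node) / len(per_node)
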