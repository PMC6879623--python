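"""Shape descriptors of nucleus (and colony) outlines, ImageJ conventions.

All descriptors follow the formulas ImageJ documents for its "Measure"
command, the de facto standard in manual-tracing workflows:

* circularity  = 4π·area / perimeter²   (1 for a circle)
* aspect ratio = major/minor axis of the second-moment fitted ellipse
* roundness    = 4·area / (π·major²)
* solidity     = area / convex-hull area
* Feret        = maximum caliper diameter (exact, over convex-hull vertices)

The fitted ellipse uses second area moments of the polygon *interior*
(uniform density), not of the vertex set, matching ImageJ's fitted-ellipse
semantics.  Area/perimeter/centroid are closed-form shoelace quantities.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .io_model import DegenerateGeometryError, ShapeDescriptors, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "polygon_area_perimeter",
    "centroid",
    "feret_diameter",
    "shape_descriptors",
    "polygon_moments",
]


def _as_vertices(outline) -> np.ndarray:
    v = np.asarray(outline, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("outline must be an (n, 2) vertex array")
    if len(v) >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]  # tolerate explicitly closed rings
    return v


def _check_simple(v: np.ndarray) -> None:
    if len(v) < 3:
        raise ValidationError("polygon needs >= 3 vertices")
    if not Polygon(v).is_valid:
        rel = v - v[0]
        cross = rel[:, 0] * rel[:, 1][:, None] - rel[:, 1] * rel[:, 0][:, None]
        if np.allclose(cross, 0.0):
            raise DegenerateGeometryError("all vertices are collinear")
        raise ValidationError("polygon is self-intersecting")


def polygon_area_perimeter(outline) -> tuple[float, float]:
    """(area, perimeter) of a simple polygon.

    Area is the absolute shoelace value; perimeter the closed vertex-chain
    length.
    """
    v = _as_vertices(outline)
    _check_simple(v)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    area = 0.5 * abs(cross.sum())
    perim = float(np.hypot(*(np.roll(v, -1, axis=0) - v).T).sum())
    return float(area), perim


def polygon_moments(outline) -> tuple[float, tuple[float, float], np.ndarray]:
    """Area, centroid and central second-moment (covariance) matrix of the
    polygon interior under uniform density.

    Closed-form shoelace sums; vertices are re-oriented so the signed area
    is positive before accumulating.
    """
    v = _as_vertices(outline)
    _check_simple(v)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = 0.5 * cross.sum()
    if a_signed == 0:
        raise DegenerateGeometryError("zero-area polygon")
    if a_signed < 0:
        return polygon_moments(v[::-1])
    area = a_signed
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    # raw second moments about the origin
    exx = ((x * x + x * x1 + x1 * x1) * cross).sum() / (12 * area)
    eyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / (12 * area)
    exy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / (24 * area)
    cov = np.array([
        [exx - cx * cx, exy - cx * cy],
        [exy - cx * cy, eyy - cy * cy],
    ])
    return float(area), (float(cx), float(cy)), cov


def centroid(outline) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon."""
    _, c, _ = polygon_moments(outline)
    return c


def feret_diameter(outline) -> float:
    """Maximum caliper (Feret) diameter: the largest vertex-pair distance,
    computed exactly over convex-hull vertices."""
    v = _as_vertices(outline)
    if len(v) < 2:
        raise ValueError("need >= 2 vertices")
    if len(v) > 3:
        try:
            v = v[ConvexHull(v).vertices]
        except QhullError:
            pass  # collinear vertex sets: fall through to all-pairs
    diff = v[:, None, :] - v[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def shape_descriptors(outline) -> ShapeDescriptors:
    """Full ImageJ-convention descriptor set for one simple polygon.

    A degenerate (zero minor axis) outline yields ``aspect_ratio = inf``
    with a warning.  Descriptors bounded by definition (circularity,
    roundness, solidity) are clamped at 1 to absorb float round-off.
    """
    area, perim = polygon_area_perimeter(outline)
    if area <= 0:
        raise DegenerateGeometryError("polygon area must be > 0")
    _, _, cov = polygon_moments(outline)
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    # ellipse with identical second moments: semi-axis a satisfies a²/4 = λ
    major = 4.0 * math.sqrt(max(eigvals[1], 0.0))
    minor = 4.0 * math.sqrt(max(eigvals[0], 0.0))
    if minor <= 0:
        logger.warning("degenerate outline: zero minor axis, aspect ratio inf")
        ar = math.inf
    else:
        ar = max(major / minor, 1.0)
    circ = min(4 * math.pi * area / perim**2, 1.0)
    roundness = min(4 * area / (math.pi * major**2), 1.0) if major > 0 else 1.0
    v = _as_vertices(outline)
    hull_area = float(Polygon(v).convex_hull.area)
    solidity = min(area / hull_area, 1.0) if hull_area > 0 else 1.0
    return ShapeDescriptors(
        perimeter=perim,
        aspect_ratio=ar,
        feret=feret_diameter(outline),
        circularity=circ,
        roundness=roundness,
        solidity=solidity,
    )
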