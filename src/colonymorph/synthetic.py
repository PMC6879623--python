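"""Synthetic colonies with the statistical structure the analysis assumes.

No imaging data ships with this package, so every stage of the pipeline is
exercised on generated colonies that emulate the measured regimes of dense
pluripotent cultures: centroid packings at ~1,800–2,600 cells/mm²,
right-skewed (lognormal) nucleus-area fields with means around
180–270 µm² and SDs of 80–110 µm², optional spatial clustering of the
small (recently divided, ~150 µm²) cells, and colony series following a
prescribed count–area power law N_c = κ·A^β.

Default parameters are the observed mid-range conditions: 22 µm lattice
spacing (≈2,400 cells/mm²) and a lognormal area field with mean 212 µm²,
SD 104 µm².  Everything is driven by one integer seed; a fixed seed gives
bit-identical colonies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint, Point

from .io_model import Colony, GenerationError, NucleusRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "generate_colony",
    "generate_colony_series",
    "triangular_lattice",
    "compact_disk_labels",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic colony.

    n_cells : number of nuclei.
    packing : ``triangular_lattice`` (ideal crystal), ``jittered_lattice``
        (crystal + uniform positional noise — the realistic default), or
        ``random_sequential`` (sequential adsorption with a hard minimum
        separation).
    spacing : µm — lattice constant / target mean separation.
    jitter : positional noise amplitude as a fraction of spacing, < 0.5 so
        neighbouring cells cannot swap.
    area_mean, area_sd : µm² — moments of the lognormal nucleus-area field.
    label_pattern : spatial arrangement of small vs large cells: ``mixed``
        (random), ``clustered`` (small cells concentrated in Gaussian
        patches), ``gradient`` (small cells toward one side).
    cluster_strength : 0 → fully mixed, 1 → arrangement fully determined by
        the patch/gradient field; monotone in between.
    n_patches : Gaussian patch centres used by ``clustered``.
    boundary : ``disk`` or convex ``hull`` of the centroids.
    """

    n_cells: int = 400
    packing: str = "jittered_lattice"
    spacing: float = 22.0
    jitter: float = 0.15
    area_mean: float = 212.0
    area_sd: float = 104.0
    label_pattern: str = "mixed"
    cluster_strength: float = 0.0
    n_patches: int = 3
    boundary: str = "disk"
    day: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not 0 <= self.jitter <= 0.49:
            raise ValueError("jitter must be in [0, 0.49]")
        if self.area_mean <= 0 or self.area_sd <= 0:
            raise ValueError("area distribution moments must be > 0")
        if self.packing not in ("triangular_lattice", "jittered_lattice",
                                "random_sequential"):
            raise ValueError(f"unknown packing {self.packing!r}")
        if self.label_pattern not in ("mixed", "clustered", "gradient"):
            raise ValueError(f"unknown label_pattern {self.label_pattern!r}")
        if not 0 <= self.cluster_strength <= 1:
            raise ValueError("cluster_strength must be in [0, 1]")


def triangular_lattice(n: int, spacing: float = 1.0) -> np.ndarray:
    """The ``n`` triangular-lattice sites nearest the origin (a compact,
    approximately disk-shaped patch), spacing ``spacing``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    # generous rectangular patch of rows, then keep the n nearest sites
    half = int(math.ceil(math.sqrt(n / (math.sqrt(3) / 2)) / 2)) + 2
    rows = np.arange(-half, half + 1)
    cols = np.arange(-half, half + 1)
    jj, ii = np.meshgrid(cols, rows)
    x = (jj + 0.5 * (ii % 2)) * spacing
    y = ii * (math.sqrt(3) / 2) * spacing
    pts = np.column_stack([x.ravel(), y.ravel()])
    r2 = (pts**2).sum(axis=1)
    order = np.lexsort((pts[:, 0], pts[:, 1], r2))  # deterministic ties
    return pts[order[:n]]


def compact_disk_labels(points: np.ndarray, n_a: int) -> np.ndarray:
    """Label the ``n_a`` points nearest the centroid ``"A"``, the rest
    ``"B"`` — a maximally segregated single-cluster configuration."""
    pts = np.asarray(points, dtype=float)
    if not 0 < n_a < len(pts):
        raise ValueError("n_a must split the points into two nonempty classes")
    r2 = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1)
    labels = np.full(len(pts), "B")
    labels[np.argsort(r2, kind="stable")[:n_a]] = "A"
    return labels


def _rsa_points(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Random sequential adsorption in a disk, hard core 0.7 × spacing."""
    site_area = math.sqrt(3) / 2 * spacing**2
    radius = math.sqrt(n * site_area / math.pi) * 1.15  # slack for RSA jamming
    rmin2 = (0.7 * spacing) ** 2
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 500 * n
    while len(pts) < n:
        if attempts >= max_attempts:
            raise GenerationError(
                f"random_sequential packing jammed at {len(pts)}/{n} cells"
            )
        attempts += 1
        r = radius * math.sqrt(rng.uniform())
        t = rng.uniform(0, 2 * math.pi)
        cand = np.array([r * math.cos(t), r * math.sin(t)])
        if all(((cand - p) ** 2).sum() >= rmin2 for p in pts):
            pts.append(cand)
    return np.array(pts)


def _lognormal(mean: float, sd: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _hexagon(center: tuple[float, float], area: float) -> np.ndarray:
    r = math.sqrt(2.0 * area / (3.0 * math.sqrt(3)))
    ang = np.arange(6) * (math.pi / 3)
    return np.column_stack([center[0] + r * np.cos(ang),
                            center[1] + r * np.sin(ang)])


def generate_colony(spec: SyntheticSpec) -> tuple[Colony, np.ndarray]:
    """Realise a synthetic colony and its ground-truth size-class labels.

    Returns ``(colony, labels)`` where ``labels[i]`` is ``"A"`` if nucleus
    ``i`` drew a below-median area (the small/recently-divided class).
    Areas are drawn from the lognormal field; under ``clustered`` or
    ``gradient`` patterns, small areas are preferentially assigned to
    positions with high patch/gradient affinity, with the mixing ratio set
    by ``cluster_strength`` (rank-matching keeps the marginal area
    distribution identical across patterns).
    """
    rng = np.random.default_rng(spec.seed)
    site_area = math.sqrt(3) / 2 * spec.spacing**2
    if spec.area_mean > site_area:
        raise GenerationError(
            f"mean nucleus area {spec.area_mean:.0f} µm² exceeds the "
            f"{site_area:.0f} µm² available per site at spacing "
            f"{spec.spacing} µm"
        )

    if spec.packing == "random_sequential":
        pts = _rsa_points(spec.n_cells, spec.spacing, rng)
    else:
        pts = triangular_lattice(spec.n_cells, spec.spacing)
        if spec.packing == "jittered_lattice" and spec.jitter > 0:
            amp = spec.jitter * spec.spacing
            pts = pts + rng.uniform(-amp, amp, size=pts.shape)

    areas_sorted = np.sort(_lognormal(spec.area_mean, spec.area_sd,
                                      spec.n_cells, rng))

    # affinity field: high affinity → small nucleus
    if spec.label_pattern == "clustered" and spec.cluster_strength > 0:
        k = max(1, min(spec.n_patches, spec.n_cells))
        centers = pts[rng.choice(spec.n_cells, size=k, replace=False)]
        sigma_p = spec.spacing * max(2.0, math.sqrt(spec.n_cells) / 4.0)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        affinity = np.exp(-d2 / (2 * sigma_p**2)).max(axis=1)
    elif spec.label_pattern == "gradient" and spec.cluster_strength > 0:
        x = pts[:, 0]
        affinity = (x.max() - x) / max(x.max() - x.min(), 1e-12)
    else:
        affinity = np.zeros(spec.n_cells)

    rank = np.argsort(np.argsort(affinity, kind="stable"), kind="stable")
    affinity_u = rank / max(spec.n_cells - 1, 1)  # uniformised affinity
    score = (spec.cluster_strength * affinity_u
             + (1 - spec.cluster_strength) * rng.uniform(size=spec.n_cells))
    # highest score → smallest area
    order = np.argsort(-score, kind="stable")
    areas = np.empty(spec.n_cells)
    areas[order] = areas_sorted

    labels = np.where(areas < np.median(areas), "A", "B")

    if spec.boundary == "disk":
        r_max = float(np.hypot(pts[:, 0], pts[:, 1]).max())
        boundary = Point(0.0, 0.0).buffer(r_max + spec.spacing / 2.0,
                                          quad_segs=64)
    elif spec.boundary == "hull":
        boundary = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(
            spec.spacing / 2.0, quad_segs=16)
    else:
        raise ValueError(f"unknown boundary {spec.boundary!r}")

    nuclei = [
        NucleusRecord(
            id=i,
            centroid=(float(pts[i, 0]), float(pts[i, 1])),
            area=float(areas[i]),
            outline=_hexagon((float(pts[i, 0]), float(pts[i, 1])),
                             float(areas[i])),
        )
        for i in range(spec.n_cells)
    ]
    colony = Colony(
        id=f"synthetic-{spec.seed}",
        day=spec.day,
        nuclei=nuclei,
        boundary=boundary,
    )
    return colony, labels


def generate_colony_series(
    n_colonies: int,
    kappa: float = 2130.0,
    beta: float = 0.93,
    area_range: tuple[float, float] = (0.1, 1.1),
    noise_sd: float = 0.05,
    seed: int = 0,
    round_counts: bool = True,
) -> np.ndarray:
    """Colony (area, count) pairs following N_c = κ·A^β with multiplicative
    lognormal noise.

    Areas [mm²] are log-uniform on ``area_range``; counts are
    round(κ·A^β·10^ε) with ε ~ Normal(0, noise_sd) in log10 units, clipped
    to ≥ 1 (with a warning) so every colony has at least one cell.
    ``round_counts=False`` keeps counts real-valued, useful for exact
    closed-form checks of the fitting stage.
    Returns an (n, 2) array of (A, N_c).
    """
    if n_colonies < 3:
        raise ValueError("need >= 3 colonies for a series")
    if beta <= 0 or kappa <= 0:
        raise ValueError("kappa and beta must be > 0")
    lo, hi = area_range
    if not 0 < lo < hi:
        raise ValueError("area_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    A = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n_colonies)
    eps = rng.normal(0.0, noise_sd, size=n_colonies) if noise_sd > 0 else 0.0
    N = kappa * A**beta * 10.0**eps
    if round_counts:
        N = np.round(N)
    if np.any(N < 1):
        logger.warning("clipping %d colonies to N_c = 1", int((N < 1).sum()))
        N = np.maximum(N, 1)
    return np.column_stack([A, N])
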