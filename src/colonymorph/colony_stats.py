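"""Per-colony summary statistics, nucleus-area PDFs and the count–area law.

A colony is summarised by the mean nucleus area ⟨α⟩ (with sample SD σ and
standard error σ/√N_c), the Delaunay neighbour statistics ⟨N_n⟩ and ⟨ℓ_n⟩,
and the mean area per cell A/N_c.  Across a colony series, the cell count
scales with colony area as N_c = κ·A^β; β ≈ 1 means cells keep a constant
footprint while the colony grows, β < 1 that larger colonies pack cells
more densely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .io_model import Colony, ColonySummary, PowerLawFit, ValidationError
from .tessellation import NeighborGraph, mean_neighbor_count, mean_neighbor_distance

logger = logging.getLogger(__name__)

__all__ = ["AreaPDF", "summarize_colony", "area_pdf", "fit_power_law",
           "boxplot_outliers"]


@dataclass(frozen=True)
class AreaPDF:
    """Normalised histogram density of nucleus areas: Σ density·width = 1."""

    bin_edges: np.ndarray  # µm²
    density: np.ndarray  # per µm²
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "density", np.asarray(self.density, float))
        total = float((self.density * np.diff(self.bin_edges)).sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"density integrates to {total}, not 1")


def summarize_colony(
    colony: Colony,
    graph: Optional[NeighborGraph] = None,
    interior_only: bool = False,
    exclude_mitotic: bool = False,
) -> ColonySummary:
    """First-order statistics of one colony.

    Mitotic cells are retained by default — their inflated areas are part
    of the measured variability — but can be excluded.  Neighbour
    statistics need a Delaunay graph over the same nuclei; for colonies too
    small to triangulate they are reported as missing.
    """
    nuclei = colony.nuclei
    if exclude_mitotic:
        nuclei = [n for n in nuclei if not n.mitotic]
    if not nuclei:
        raise ValidationError(f"colony {colony.id}: no nuclei to summarise")
    areas = np.array([n.area for n in nuclei])
    n_c = len(areas)
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1)) if n_c > 1 else 0.0
    se = sd / math.sqrt(n_c)

    mean_nn = mean_ln = None
    if graph is not None and graph.n_nodes >= 3 and graph.n_edges > 0:
        mean_nn, _ = mean_neighbor_count(graph, interior_only=interior_only)
        mean_ln, _ = mean_neighbor_distance(graph, interior_only=interior_only)
    else:
        logger.warning("colony %s: neighbour statistics unavailable "
                       "(too few cells or no graph)", colony.id)

    apc = None
    if colony.area is not None:
        apc = colony.area * 1e6 / colony.n_cells  # mm² → µm²
    return ColonySummary(
        colony_id=colony.id,
        n_cells=n_c,
        mean_area=mean,
        sd_area=sd,
        se_area=se,
        mean_neighbors=mean_nn,
        mean_neighbor_distance=mean_ln,
        area_per_cell=apc,
    )


def area_pdf(areas, bin_width: float = 25.0, start: float = 0.0) -> AreaPDF:
    """Probability density function of nucleus areas.

    Fixed-width bins (default 25 µm²) from ``start``, extended to cover the
    largest observation; density normalised so it integrates to 1.
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 samples for a PDF")
    if np.any(a < 0):
        raise ValidationError("negative areas in input")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = max(1, int(np.ceil((a.max() - start) / bin_width + 1e-12)))
    edges = start + bin_width * np.arange(n_bins + 1)
    density, edges = np.histogram(a, bins=edges, density=True)
    return AreaPDF(bin_edges=edges, density=density, n=a.size)


def fit_power_law(
    colonies: Sequence[tuple[float, float]],
    method: str = "loglog",
) -> PowerLawFit:
    """Fit N_c = κ·A^β to (A [mm²], N_c) pairs.

    Default is ordinary least squares of log10(N_c) on log10(A) — the
    straight line on a log-log plot — with R² in log space.  ``method="nls"``
    fits in natural space by nonlinear least squares instead (the two
    differ under heteroscedastic noise); its R² is also reported in log
    space for comparability.
    """
    pairs = np.asarray(colonies, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise ValueError("need >= 3 (area, count) pairs")
    A, N = pairs[:, 0], pairs[:, 1]
    if np.any(A <= 0) or np.any(N <= 0):
        raise ValueError("areas and counts must be positive")
    logA, logN = np.log10(A), np.log10(N)

    if method == "loglog":
        res = stats.linregress(logA, logN)
        kappa, beta = 10.0**res.intercept, float(res.slope)
        r2 = float(res.rvalue**2)
    elif method == "nls":
        res0 = stats.linregress(logA, logN)
        (kappa, beta), _ = optimize.curve_fit(
            lambda a, k, b: k * a**b, A, N,
            p0=(10.0**res0.intercept, res0.slope),
        )
        pred = np.log10(kappa * A**beta)
        ss_res = ((logN - pred) ** 2).sum()
        ss_tot = ((logN - logN.mean()) ** 2).sum()
        r2 = float(1 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return PowerLawFit(kappa=float(kappa), beta=float(beta),
                       r_squared=r2, n_colonies=len(pairs))


def boxplot_outliers(values) -> np.ndarray:
    """Tukey boxplot outlier flags: outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use the linear-interpolation convention (numpy's default,
    Hyndman–Fan type 7) — stated because flags can shift at small n under
    other conventions.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for boxplot fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
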