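"""Domain types and file I/O for colony morphometry.

All coordinates are continuous Cartesian micrometres with the origin at the
image top-left and y increasing downward (the convention of ImageJ exports);
areas are µm² for nuclei and mm² for whole colonies.  Import is the only
place where pixel units exist: linear quantities scale with ``pixel_scale``
(µm/px) and areal quantities with ``pixel_scale**2``.

Readers accept two CSV dialects:

``imagej_measure``
    The header row of an ImageJ "Measure" export: ``X``, ``Y``, ``Area``
    mandatory; ``Perim.``, ``AR``, ``Feret``, ``Circ.``, ``Round``,
    ``Solidity`` and ``Mitotic`` are picked up when present; anything else
    is ignored with a logged notice (ImageJ versions drift).

``plain_xy``
    Lower-case ``x``, ``y`` (+ optional ``area``) columns, for synthetic or
    hand-made tables.

Boundary polygons come either as a CSV of ``x,y`` vertex rows or as a WKT
``POLYGON`` string; they are validated as simple polygons and normalised to
counter-clockwise vertex order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "DegenerateGeometryError",
    "GenerationError",
    "ShapeDescriptors",
    "NucleusRecord",
    "Colony",
    "ColonySummary",
    "PowerLawFit",
    "SegregationProfile",
    "read_nuclei_table",
    "read_boundary",
    "write_summary",
    "read_summaries",
    "read_profile",
    "read_fit",
]


class FormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A record or geometry violates a domain invariant."""


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate to process (collinear points, zero area...)."""


class GenerationError(RuntimeError):
    """A synthetic specification cannot be realised (e.g. infeasible density)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeDescriptors:
    """ImageJ-convention shape descriptors of a single outline.

    perimeter : µm — closed vertex-chain length.
    aspect_ratio : major/minor axis of the second-moment (fitted) ellipse, ≥ 1;
        ``inf`` for a degenerate (zero-thickness) outline.
    feret : µm — maximum caliper diameter.
    circularity : 4π·area/perimeter², in (0, 1].
    roundness : 4·area/(π·major²), in (0, 1].
    solidity : area / convex-hull area, in (0, 1].
    """

    perimeter: float
    aspect_ratio: float
    feret: float
    circularity: float
    roundness: float
    solidity: float

    def __post_init__(self) -> None:
        tol = 1e-9
        if self.circularity > 1 + tol:
            raise ValidationError(f"circularity {self.circularity} > 1")
        if self.solidity > 1 + tol:
            raise ValidationError(f"solidity {self.solidity} > 1")
        if not math.isinf(self.aspect_ratio) and self.aspect_ratio < 1 - tol:
            raise ValidationError(f"aspect_ratio {self.aspect_ratio} < 1")


@dataclass(frozen=True)
class NucleusRecord:
    """One manually traced nucleus.

    ``area`` is authoritative: when an outline is also present its shoelace
    area may disagree slightly (tracing software rounds); a discrepancy
    above 1% is logged but the tabulated area wins.
    """

    id: int
    centroid: tuple[float, float]  # µm
    area: float  # µm²
    outline: Optional[np.ndarray] = None  # (k, 2) vertices, µm
    descriptors: Optional[ShapeDescriptors] = None
    mitotic: bool = False

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError(f"nucleus {self.id}: area {self.area} must be > 0")
        if self.outline is not None:
            out = np.asarray(self.outline, dtype=float)
            if out.ndim != 2 or out.shape[1] != 2 or out.shape[0] < 3:
                raise ValidationError(
                    f"nucleus {self.id}: outline must be (k>=3, 2) vertices"
                )
            poly = Polygon(out)
            if not poly.is_valid:
                raise ValidationError(f"nucleus {self.id}: outline is not simple")
            object.__setattr__(self, "outline", out)
            rel = abs(poly.area - self.area) / self.area
            if rel > 0.01:
                logger.warning(
                    "nucleus %d: outline area %.2f differs from tabulated area "
                    "%.2f by %.1f%% (tabulated value kept)",
                    self.id, poly.area, self.area, 100 * rel,
                )


@dataclass
class Colony:
    """A colony: its traced nuclei, boundary and bulk geometry.

    area : mm² (the conventional unit for whole colonies).  If omitted and a
    boundary polygon is given it is derived from the boundary.
    ``n_cells`` supports count-only colonies (boundary traced, nuclei not).
    """

    id: str
    day: int
    nuclei: list[NucleusRecord] = field(default_factory=list)
    boundary: Optional[Polygon] = None  # vertices in µm
    area: Optional[float] = None  # mm²
    perimeter: Optional[float] = None  # mm
    n_cells: Optional[int] = None

    def __post_init__(self) -> None:
        if self.boundary is not None:
            if self.area is None:
                self.area = self.boundary.area / 1e6
            if self.perimeter is None:
                self.perimeter = self.boundary.length / 1e3
            bnd = self.boundary.buffer(1e-9)
            outside = [
                n.id for n in self.nuclei if not bnd.covers(Point(n.centroid))
            ]
            if outside:
                raise ValidationError(
                    f"colony {self.id}: centroids outside boundary: {outside}"
                )
        if self.n_cells is None:
            self.n_cells = len(self.nuclei)
        elif self.nuclei and self.n_cells != len(self.nuclei):
            raise ValidationError(
                f"colony {self.id}: n_cells={self.n_cells} but "
                f"{len(self.nuclei)} nuclei given"
            )
        if self.area is not None and not self.area > 0:
            raise ValidationError(f"colony {self.id}: area must be > 0")
        if self.n_cells < 1:
            raise ValidationError(f"colony {self.id}: needs at least one cell")

    @property
    def centroids(self) -> np.ndarray:
        return np.array([n.centroid for n in self.nuclei], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([n.area for n in self.nuclei], dtype=float)


@dataclass(frozen=True)
class ColonySummary:
    """Per-colony first-order statistics.

    mean_area ⟨α⟩ and sd_area σ are over nucleus areas (sample SD, n−1);
    se_area = σ/√N_c; mean_neighbors ⟨N_n⟩ and mean_neighbor_distance ⟨ℓ_n⟩
    come from the Delaunay graph; area_per_cell = A/N_c in µm².
    """

    colony_id: str
    n_cells: int
    mean_area: float
    sd_area: float
    se_area: float
    mean_neighbors: Optional[float] = None
    mean_neighbor_distance: Optional[float] = None
    area_per_cell: Optional[float] = None

    def __post_init__(self) -> None:
        expected_se = self.sd_area / math.sqrt(self.n_cells)
        if not math.isclose(self.se_area, expected_se, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("se_area must equal sd_area/sqrt(n_cells)")


@dataclass(frozen=True)
class PowerLawFit:
    """Count–area scaling law N_c = κ·A^β (A in mm²), with log-space R²."""

    kappa: float
    beta: float
    r_squared: float
    n_colonies: int = 0


@dataclass(frozen=True)
class SegregationProfile:
    """δ(α*) over a threshold grid, with per-threshold class/edge counts and,
    optionally, bootstrap-null quantiles (low, median, high per threshold).

    ``delta`` holds NaN at thresholds where a class is empty.
    """

    colony_id: str
    thresholds: np.ndarray  # α*, µm²
    delta: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    n_ab: np.ndarray
    null_low: Optional[np.ndarray] = None
    null_median: Optional[np.ndarray] = None
    null_high: Optional[np.ndarray] = None
    null_mean: Optional[np.ndarray] = None
    n_boot: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("thresholds", "delta", "n_a", "n_b", "n_ab",
                     "null_low", "null_median", "null_high", "null_mean"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly ascending")
        finite = np.isfinite(self.delta)
        if np.any(self.delta[finite] > 1 + 1e-9):
            raise ValidationError("delta cannot exceed 1")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_IMAGEJ_REQUIRED = ("X", "Y", "Area")
_IMAGEJ_KNOWN = {"X", "Y", "Area", "Perim.", "AR", "Feret", "Circ.",
                 "Round", "Solidity", "Mitotic", " "}  # " " = ImageJ row index


def read_nuclei_table(
    path: Union[str, Path],
    pixel_scale: float,
    dialect: str = "imagej_measure",
) -> list[NucleusRecord]:
    """Read a nuclei table, converting pixels to µm (and px² to µm²).

    Parameters
    ----------
    path : CSV file with a header row.
    pixel_scale : µm per pixel (> 0); e.g. 1.36 at 5× or 0.67 at 10×
        magnification.  Pass 1.0 for tables already in µm.
    dialect : ``imagej_measure`` or ``plain_xy``.
    """
    if pixel_scale <= 0:
        raise ValueError(f"pixel_scale must be > 0, got {pixel_scale}")
    if dialect not in ("imagej_measure", "plain_xy"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("nuclei table %s is empty", path)
        return []
    if df.empty:
        logger.warning("nuclei table %s has a header but no rows", path)
        return []

    if dialect == "imagej_measure":
        cols = {"x": "X", "y": "Y", "area": "Area"}
        for col in _IMAGEJ_REQUIRED:
            if col not in df.columns:
                raise FormatError(
                    f"{path}: imagej_measure dialect requires column {col!r}"
                )
        unknown = [c for c in df.columns if c not in _IMAGEJ_KNOWN
                   and not str(c).startswith("Unnamed")]
        if unknown:
            logger.info("%s: ignoring unrecognised columns %s", path, unknown)
    else:
        lower = {str(c).lower(): c for c in df.columns}
        for col in ("x", "y"):
            if col not in lower:
                raise FormatError(
                    f"{path}: plain_xy dialect requires column {col!r}"
                )
        cols = {"x": lower["x"], "y": lower["y"],
                "area": lower.get("area")}

    s, s2 = pixel_scale, pixel_scale**2
    records: list[NucleusRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        area_px = float(row[cols["area"]]) if cols["area"] is not None else 1.0 / s2
        if not area_px > 0:
            raise ValidationError(f"{path} row {i}: non-positive area {area_px}")
        desc = None
        if dialect == "imagej_measure" and "Circ." in df.columns:
            try:
                desc = ShapeDescriptors(
                    perimeter=float(row.get("Perim.", np.nan)) * s,
                    aspect_ratio=float(row.get("AR", np.nan)),
                    feret=float(row.get("Feret", np.nan)) * s,
                    circularity=float(row["Circ."]),
                    roundness=float(row.get("Round", np.nan)),
                    solidity=float(row.get("Solidity", np.nan)),
                )
            except (KeyError, TypeError):
                desc = None
        records.append(NucleusRecord(
            id=i,
            centroid=(float(row[cols["x"]]) * s, float(row[cols["y"]]) * s),
            area=area_px * s2,
            descriptors=desc,
            mitotic=bool(row.get("Mitotic", False)),
        ))
    return records


def read_boundary(path: Union[str, Path], pixel_scale: float = 1.0) -> Polygon:
    """Read a colony boundary polygon (CSV of x,y rows or a WKT POLYGON).

    Returns a simple shapely polygon in µm with counter-clockwise vertex
    order (shoelace-positive in the y-down image frame).
    """
    if pixel_scale <= 0:
        raise ValueError(f"pixel_scale must be > 0, got {pixel_scale}")
    path = Path(path)
    text = path.read_text().strip()
    if text.upper().startswith("POLYGON"):
        poly = shapely.from_wkt(text)
        coords = np.asarray(poly.exterior.coords)[:-1]
    else:
        df = pd.read_csv(path, header=None if _looks_headerless(text) else 0)
        coords = df.iloc[:, :2].to_numpy(dtype=float)
    if coords.shape[0] < 3:
        raise ValidationError(f"{path}: boundary needs >= 3 vertices")
    coords = coords * pixel_scale
    poly = Polygon(coords)
    if not poly.is_valid or poly.area == 0:
        raise ValidationError(f"{path}: boundary polygon is self-intersecting "
                              "or degenerate")
    return orient(poly, sign=1.0)


def _looks_headerless(text: str) -> bool:
    first = text.splitlines()[0]
    try:
        [float(tok) for tok in first.split(",")[:2]]
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# writers (lossless round-trip: CSV via repr-precision floats, JSON for
# structured results)
# ---------------------------------------------------------------------------


def write_summary(
    records: Union[Sequence[ColonySummary], SegregationProfile, PowerLawFit],
    path: Union[str, Path],
) -> None:
    """Write results to disk: ColonySummary lists as CSV, SegregationProfile
    and PowerLawFit as JSON.  All floats at full (round-trippable) precision.
    """
    path = Path(path)
    if isinstance(records, SegregationProfile):
        payload = {}
        for f in dataclasses.fields(records):
            v = getattr(records, f.name)
            payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif isinstance(records, PowerLawFit):
        path.write_text(
            json.dumps(dataclasses.asdict(records), indent=1, sort_keys=True) + "\n"
        )
    else:
        fields = [f.name for f in dataclasses.fields(ColonySummary)]
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=fields)
        df.to_csv(path, index=False, float_format=None)


def read_summaries(path: Union[str, Path]) -> list[ColonySummary]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for k in ("mean_neighbors", "mean_neighbor_distance", "area_per_cell"):
            if k in d and pd.isna(d[k]):
                d[k] = None
        out.append(ColonySummary(**d))
    return out


def read_profile(path: Union[str, Path]) -> SegregationProfile:
    payload = json.loads(Path(path).read_text())
    return SegregationProfile(**payload)


def read_fit(path: Union[str, Path]) -> PowerLawFit:
    return PowerLawFit(**json.loads(Path(path).read_text()))
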