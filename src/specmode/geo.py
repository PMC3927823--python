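"""Geographic ranges as convex hulls and pairwise range-overlap proportions.

Species ranges are estimated from georeferenced point localities: the
localities are projected onto a local planar frame (equirectangular, in km),
the convex hull of each species' points is taken as its range polygon, and
the overlap between two species is the area of intersection divided by the
area of the *smaller* range, so a value of 1 means the narrower-ranged
species is completely embedded within the other.

The convex hull is the "tightly-stretched elastic band" range estimate: it
deliberately over-estimates range extent, which makes a finding of allopatry
(zero overlap) conservative.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: two degenerate (point/segment) ranges count as co-occurring when any
#: locality pair coincides within this distance (km)
COINCIDENCE_TOL_KM = 1e-6


class InputFormatError(ValueError):
    """A file is structurally unusable (missing columns, unparseable)."""


class ValidationError(ValueError):
    """Rows were read but violate domain invariants."""


@dataclass(frozen=True)
class PointLocality:
    """One georeferenced occurrence record for a species."""

    species_id: str
    longitude: float
    latitude: float
    precision_radius_m: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"longitude {self.longitude} outside [-180, 180] "
                f"for species {self.species_id!r}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"latitude {self.latitude} outside [-90, 90] "
                f"for species {self.species_id!r}"
            )


@dataclass(frozen=True)
class ProjectedPoint:
    """Locality in the planar analysis frame: km east (x) and north (y)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("projected coordinates must be finite")


@dataclass
class ConvexRange:
    """A species range as a convex polygon in the projected frame.

    ``vertices`` are ordered counter-clockwise with collinear boundary
    points removed.  A range built from fewer than 3 non-collinear
    localities is *degenerate*: it has zero area and overlap against it is
    decided by locality membership rather than polygon intersection.
    """

    species_id: str
    vertices: list[ProjectedPoint]
    area: float
    n_localities: int
    degenerate: bool
    localities: list[ProjectedPoint] = field(default_factory=list, repr=False)

    def polygon(self) -> _ShapelyPolygon:
        if self.degenerate:
            raise ValueError(f"range for {self.species_id!r} is degenerate")
        return _ShapelyPolygon([(p.x, p.y) for p in self.vertices])


@dataclass
class OverlapMatrix:
    """Symmetric species-by-species matrix of range-overlap proportions."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match species list")

    def get(self, a: str, b: str) -> float:
        i = self.species_ids.index(a)
        j = self.species_ids.index(b)
        return float(self.values[i, j])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["species"] + self.species_ids)
            for sp, row in zip(self.species_ids, self.values):
                w.writerow([sp] + [f"{v:.10g}" for v in row])

    @classmethod
    def from_csv(cls, path: str | Path) -> "OverlapMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        ids = rows[0][1:]
        vals = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(ids, vals)


# ---------------------------------------------------------------------------
# reading and projecting localities


def read_localities(path: str | Path) -> list[PointLocality]:
    """Read a locality CSV with columns species, longitude, latitude.

    Optional columns ``precision_m`` and ``source`` are carried through.
    Rows violating coordinate bounds raise :class:`ValidationError` naming
    the offending row; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"locality file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"empty locality file: {path}", stacklevel=2)
            return []
        missing = {"species", "longitude", "latitude"} - set(reader.fieldnames)
        if missing:
            raise InputFormatError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        out: list[PointLocality] = []
        for i, row in enumerate(reader, start=2):
            try:
                prec = row.get("precision_m")
                out.append(
                    PointLocality(
                        species_id=row["species"].strip(),
                        longitude=float(row["longitude"]),
                        latitude=float(row["latitude"]),
                        precision_radius_m=float(prec) if prec not in (None, "") else None,
                        source=row.get("source", "") or "",
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    if not out:
        warnings.warn(f"no locality rows in {path}", stacklevel=2)
    return out


def project(
    localities: Sequence[PointLocality],
    reference_latitude: float | str = "auto",
) -> list[ProjectedPoint]:
    """Project lon/lat localities onto a planar equirectangular frame in km.

    x = R cos(lat0) (lon - lon0) pi/180, y = R (lat - lat0) pi/180 with
    R = 6371 km.  With ``reference_latitude="auto"`` the frame is anchored
    at the mean longitude/latitude of the input; a numeric value fixes the
    reference latitude (the longitude origin stays at the data mean).
    Adequate for study extents of a few hundred km.
    """
    if not localities:
        raise ValueError("cannot project an empty locality list")
    lons = np.array([p.longitude for p in localities])
    lats = np.array([p.latitude for p in localities])
    lon0 = float(lons.mean())
    if reference_latitude == "auto":
        lat0 = float(lats.mean())
    else:
        lat0 = float(reference_latitude)
    k = math.pi / 180.0 * EARTH_RADIUS_KM
    xs = k * math.cos(math.radians(lat0)) * (lons - lon0)
    ys = k * (lats - lat0)
    return [ProjectedPoint(float(x), float(y)) for x, y in zip(xs, ys)]


def unproject(
    points: Sequence[tuple[float, float]], lat0: float, lon0: float
) -> list[tuple[float, float]]:
    """Inverse of :func:`project` for a known reference: (x,y) km -> (lon,lat)."""
    k = math.pi / 180.0 * EARTH_RADIUS_KM
    out = []
    for x, y in points:
        lon = lon0 + x / (k * math.cos(math.radians(lat0)))
        lat = lat0 + y / k
        out.append((lon, lat))
    return out


# ---------------------------------------------------------------------------
# convex hull construction (monotone chain)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _monotone_chain(pts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Andrew's monotone chain; returns CCW hull without collinear vertices."""
    pts = sorted(set(pts))
    if len(pts) <= 2:
        return pts
    lower: list[tuple[float, float]] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def _shoelace(verts: list[tuple[float, float]]) -> float:
    n = len(verts)
    s = 0.0
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def build_hull(points: Sequence[ProjectedPoint], species_id: str) -> ConvexRange:
    """Convex hull of projected localities for one species.

    Fewer than 3 non-collinear points produce a *degenerate* range (area 0)
    rather than an error; real datasets (>= 6 localities per species) always
    yield proper polygons, but synthetic or sparse data may not.
    """
    if not points:
        raise ValueError(f"no points for species {species_id!r}")
    coords = [(p.x, p.y) for p in points]
    hull = _monotone_chain(coords)
    if len(hull) < 3:
        return ConvexRange(
            species_id=species_id,
            vertices=[ProjectedPoint(*c) for c in hull],
            area=0.0,
            n_localities=len(points),
            degenerate=True,
            localities=list(points),
        )
    area = _shoelace(hull)
    assert area > 0.0  # CCW by construction
    return ConvexRange(
        species_id=species_id,
        vertices=[ProjectedPoint(*c) for c in hull],
        area=float(area),
        n_localities=len(points),
        degenerate=False,
        localities=list(points),
    )


def ranges_from_localities(
    localities: Sequence[PointLocality],
    reference_latitude: float | str = "auto",
) -> list[ConvexRange]:
    """Project all localities in one shared frame and hull them per species."""
    proj = project(localities, reference_latitude)
    by_sp: dict[str, list[ProjectedPoint]] = {}
    for loc, pp in zip(localities, proj):
        by_sp.setdefault(loc.species_id, []).append(pp)
    return [build_hull(pts, sp) for sp, pts in sorted(by_sp.items())]


# ---------------------------------------------------------------------------
# overlap


def intersection_area(a: ConvexRange, b: ConvexRange) -> float:
    """Area (km^2) of the intersection of two non-degenerate convex ranges."""
    if a.degenerate or b.degenerate:
        raise ValueError(
            "intersection_area requires non-degenerate ranges; "
            "use overlap_proportion for degenerate cases"
        )
    return float(a.polygon().intersection(b.polygon()).area)


def overlap_proportion(a: ConvexRange, b: ConvexRange) -> float:
    """Range overlap in [0, 1]: intersection area over the smaller area.

    Degenerate ranges (points/segments) are scored by locality membership:
    against a polygon, the fraction of the degenerate range's localities
    that fall inside or on the polygon; two degenerate ranges overlap fully
    (1) only when some locality pair coincides within a 1e-6 km tolerance.
    """
    # canonical argument order so the result is exactly symmetric
    if (b.area, b.species_id) < (a.area, a.species_id):
        a, b = b, a
    if not a.degenerate and not b.degenerate:
        inter = intersection_area(a, b)
        prop = inter / min(a.area, b.area)
        return float(min(1.0, max(0.0, prop)))
    if a.degenerate and b.degenerate:
        for p in a.localities:
            for q in b.localities:
                if math.hypot(p.x - q.x, p.y - q.y) <= COINCIDENCE_TOL_KM:
                    return 1.0
        return 0.0
    deg, poly = (a, b) if a.degenerate else (b, a)
    shp = poly.polygon()
    inside = sum(
        1
        for p in deg.localities
        if shp.covers(_ShapelyPoint(p.x, p.y))
    )
    return inside / len(deg.localities)


def overlap_matrix(ranges: Sequence[ConvexRange]) -> OverlapMatrix:
    """All pairwise overlap proportions; symmetric with unit diagonal."""
    ids = [r.species_id for r in ranges]
    if len(ids) < 2:
        raise ValueError("need at least two ranges")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species_id in range list")
    n = len(ranges)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = overlap_proportion(ranges[i], ranges[j])
    return OverlapMatrix(ids, M)


# ---------------------------------------------------------------------------
# writers


def write_range_vertices(ranges: Sequence[ConvexRange], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "vertex_index", "x_km", "y_km"])
        for r in ranges:
            for i, v in enumerate(r.vertices):
                w.writerow([r.species_id, i, f"{v.x:.6f}", f"{v.y:.6f}"])


def write_range_summary(ranges: Sequence[ConvexRange], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "n_localities", "area_km2", "degenerate"])
        for r in ranges:
            w.writerow([r.species_id, r.n_localities, f"{r.area:.6f}", int(r.degenerate)])
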