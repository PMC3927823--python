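"""Synthetic data with the statistical structure the analysis assumes.

Generates a two-clade dated tree, species range polygons under a
*vicariant* regime (each speciation splits the parent range along a random
chord, so daughters are born allopatric) or a *sympatric* regime (daughters
inherit the full parent range, born fully overlapping), point localities
sampled within ranges with map-precision noise, and four correlated
positive traits evolving by Brownian motion on the log scale, with an extra
divergent mean shift at sympatric speciation events — the expectation that
speciation in sympatry is accompanied by adaptive morphological divergence.

Every generator draws from a single numpy Generator seeded from the
config, so datasets are exactly reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon, box

from .cladestats import CladeAssignment
from .geo import PointLocality, unproject
from .morpho import TRAIT_NAMES, SpecimenRecord
from .trees import DatedTree, Node

_SPLIT_RETRIES = 50

#: baseline species trait means (mm): capitulum length/width, leaf
#: length/width of a typical paper daisy
BASE_TRAIT_MEANS_MM = (8.0, 5.0, 20.0, 2.0)


@dataclass
class SimulationConfig:
    """All generative parameters for the synthetic harness.

    Defaults mirror the study design being emulated: two clades of 6 and 4
    species, ~20 localities and 20 measured specimens per species, locality
    noise on the order of the 5-10 km map precision of the original
    georeferencing, clade A vicariant and clade B sympatric with an
    adaptive divergence boost.
    """

    n_species_per_clade: tuple[int, int] = (6, 4)
    birth_rate: float = 1.0  # speciations per lineage per Ma
    range_mode: dict = field(
        default_factory=lambda: {"A": "vicariant", "B": "sympatric"}
    )
    root_range_km: tuple[float, float] = (300.0, 200.0)  # width, height
    split_fraction: float = 0.5  # area ratio of vicariant daughters
    dispersal_sd: float = 10.0  # km per sqrt(Ma), per coordinate
    localities_per_species: int = 20
    locality_noise_sd: float = 5.0  # km
    bm_rate: float = 0.02  # log-trait variance per Ma
    trait_correlation: float = 0.5  # BM cross-trait correlation
    sympatric_divergence_boost: float = 3.0  # kappa, in units of sqrt(bm_rate)
    specimens_per_species: int = 20
    measurement_cv: float = 0.1  # lognormal specimen noise
    seed: int = 0
    reference_latitude: float = -29.5  # frame origin for lon/lat output
    reference_longitude: float = 29.0

    def __post_init__(self) -> None:
        if min(self.n_species_per_clade) < 2:
            raise ValueError("each clade needs >= 2 species")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        for name in ("birth_rate", "dispersal_sd", "locality_noise_sd",
                     "bm_rate", "sympatric_divergence_boost", "measurement_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        modes = set(self.range_mode.values())
        if not modes <= {"vicariant", "sympatric"}:
            raise ValueError(f"unknown range modes: {modes}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_species_per_clade"] = list(self.n_species_per_clade)
        d["root_range_km"] = list(self.root_range_km)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "n_species_per_clade" in d:
            d["n_species_per_clade"] = tuple(d["n_species_per_clade"])
        if "root_range_km" in d:
            d["root_range_km"] = tuple(d["root_range_km"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    tree: DatedTree
    true_ranges: dict[str, Polygon]
    localities: list[PointLocality]
    specimens: list[SpecimenRecord]
    clades: CladeAssignment
    provenance: dict


# ---------------------------------------------------------------------------
# tree


def _yule_clade(n: int, lam: float, rng: np.random.Generator,
                prefix: str) -> tuple[Node, float]:
    """Pure-birth clade conditioned on n tips; returns (crown node, crown age).

    Lineages split at Exp(k*lam) waiting times; after the n-th lineage one
    further waiting time elapses to set the present.
    """
    t = 0.0
    root = Node("", 0.0, [])
    active = [root]
    events: list[tuple[Node, float]] = []
    for k in range(1, n):
        t += rng.exponential(1.0 / (k * lam))
        node = active.pop(int(rng.integers(len(active))))
        c1, c2 = Node("", 0.0, []), Node("", 0.0, [])
        node.children = [c1, c2]
        events.append((node, t))
        active.extend([c1, c2])
    t += rng.exponential(1.0 / (n * lam))
    for node, ts in events:
        node.age = t - ts
    for i, tip in enumerate(active):
        tip.age = 0.0
        tip.label = f"{prefix}{i + 1}"
    return root, root.age


def simulate_tree(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> DatedTree:
    """Two Yule clades (labelled A*, B*) joined at a common root.

    The root age is the larger clade crown age plus one expected two-lineage
    waiting time, 1/(2*birth_rate); the tree is ultrametric.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_species_per_clade
    lam = config.birth_rate
    clade_a, age_a = _yule_clade(n_a, lam, rng, "A")
    clade_b, age_b = _yule_clade(n_b, lam, rng, "B")
    root_age = max(age_a, age_b) + 1.0 / (2.0 * lam)
    root = Node("", root_age, [clade_a, clade_b])
    return DatedTree(root)


def clade_assignment(tree: DatedTree) -> CladeAssignment:
    """Clade labels from tip prefixes: A* -> 'A', B* -> 'B'."""
    return CladeAssignment({lab: lab[0] for lab in tree.tip_labels})


# ---------------------------------------------------------------------------
# ranges


def _split_polygon(poly: Polygon, fraction: float,
                   rng: np.random.Generator) -> tuple[Polygon, Polygon]:
    """Split a convex polygon by a random-direction chord into parts with
    area ratio fraction : (1 - fraction); offset found by bisection."""
    for _ in range(_SPLIT_RETRIES):
        theta = rng.uniform(0.0, math.pi)
        nx, ny = -math.sin(theta), math.cos(theta)
        verts = np.asarray(poly.exterior.coords)
        proj = verts[:, 0] * nx + verts[:, 1] * ny
        lo, hi = float(proj.min()), float(proj.max())
        if hi - lo < 1e-9:
            continue
        target = fraction * poly.area
        span = max(abs(v) for v in (*verts[:, 0], *verts[:, 1])) + (hi - lo) + 1.0

        def halfplane_area(c: float) -> float:
            # half-plane {p . n <= c} realized as a large clipped box
            dx, dy = math.cos(theta), math.sin(theta)
            p0 = (c * nx, c * ny)
            corners = [
                (p0[0] + dx * span - nx * 2 * span, p0[1] + dy * span - ny * 2 * span),
                (p0[0] - dx * span - nx * 2 * span, p0[1] - dy * span - ny * 2 * span),
                (p0[0] - dx * span, p0[1] - dy * span),
                (p0[0] + dx * span, p0[1] + dy * span),
            ]
            return poly.intersection(Polygon(corners)).area

        a, b = lo, hi
        for _ in range(60):
            mid = 0.5 * (a + b)
            if halfplane_area(mid) < target:
                a = mid
            else:
                b = mid
        c = 0.5 * (a + b)
        dx, dy = math.cos(theta), math.sin(theta)
        p0 = (c * nx, c * ny)
        corners_lo = [
            (p0[0] + dx * span - nx * 2 * span, p0[1] + dy * span - ny * 2 * span),
            (p0[0] - dx * span - nx * 2 * span, p0[1] - dy * span - ny * 2 * span),
            (p0[0] - dx * span, p0[1] - dy * span),
            (p0[0] + dx * span, p0[1] + dy * span),
        ]
        corners_hi = [
            (p0[0] - dx * span, p0[1] - dy * span),
            (p0[0] + dx * span, p0[1] + dy * span),
            (p0[0] + dx * span + nx * 2 * span, p0[1] + dy * span + ny * 2 * span),
            (p0[0] - dx * span + nx * 2 * span, p0[1] - dy * span + ny * 2 * span),
        ]
        part1 = poly.intersection(Polygon(corners_lo))
        part2 = poly.intersection(Polygon(corners_hi))
        if (
            part1.geom_type == "Polygon" and part2.geom_type == "Polygon"
            and part1.area > 1e-6 * poly.area and part2.area > 1e-6 * poly.area
        ):
            return part1, part2
    raise RuntimeError("could not find a valid splitting chord")


def simulate_ranges(tree: DatedTree, config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> dict[str, Polygon]:
    """True range polygons per species under per-clade range regimes.

    The root range is split vicariantly between the two clades (the clades
    of the emulated system occupy largely separate sectors); within a clade
    each speciation either splits the parent polygon (vicariant: daughters
    born allopatric) or copies it (sympatric: daughters born fully
    overlapping).  After birth, each daughter polygon is translated by a
    Gaussian displacement of sd dispersal_sd * sqrt(branch length) per
    coordinate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w, h = config.root_range_km
    root_poly = box(-w / 2.0, -h / 2.0, w / 2.0, h / 2.0)
    ranges: dict[str, Polygon] = {}

    def descend(node: Node, poly: Polygon, mode: str) -> None:
        if node.is_tip:
            ranges[node.label] = poly
            return
        if mode == "vicariant":
            parts = _split_polygon(poly, config.split_fraction, rng)
        else:
            parts = (poly, poly)
        for child, part in zip(node.children, parts):
            bl = node.age - child.age
            disp = rng.normal(0.0, config.dispersal_sd * math.sqrt(max(bl, 0.0)), 2)
            descend(child, affinity.translate(part, disp[0], disp[1]), mode)

    root = tree.root
    part_a, part_b = _split_polygon(root_poly, config.split_fraction, rng)
    for child, part, clade in zip(root.children, (part_a, part_b), ("A", "B")):
        bl = root.age - child.age
        disp = rng.normal(0.0, config.dispersal_sd * math.sqrt(max(bl, 0.0)), 2)
        descend(child, affinity.translate(part, disp[0], disp[1]),
                config.range_mode[clade])
    return ranges


def sample_localities(polygon: Polygon, species_id: str,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> list[PointLocality]:
    """Uniform points in the polygon (rejection sampling) plus isotropic
    Gaussian map-precision noise, back-projected to lon/lat."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if polygon.area <= 0:
        raise ValueError(f"degenerate polygon for {species_id!r}")
    minx, miny, maxx, maxy = polygon.bounds
    pts: list[tuple[float, float]] = []
    from shapely.geometry import Point as _P

    while len(pts) < config.localities_per_species:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if polygon.covers(_P(x, y)):
            noise = rng.normal(0.0, config.locality_noise_sd, 2)
            pts.append((x + noise[0], y + noise[1]))
    lonlat = unproject(pts, config.reference_latitude, config.reference_longitude)
    return [
        PointLocality(
            species_id=species_id,
            longitude=lon,
            latitude=lat,
            precision_radius_m=1000.0 * config.locality_noise_sd,
            source="synthetic",
        )
        for lon, lat in lonlat
    ]


# ---------------------------------------------------------------------------
# traits


def _bm_chol(config: SimulationConfig) -> np.ndarray:
    p = len(TRAIT_NAMES)
    C = np.full((p, p), config.trait_correlation)
    np.fill_diagonal(C, 1.0)
    return np.linalg.cholesky(config.bm_rate * C)


def simulate_traits_and_specimens(
    tree: DatedTree, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SpecimenRecord]:
    """Brownian log-trait evolution plus divergent shifts at sympatric splits.

    Species mean log-traits follow correlated BM along branches (rate
    bm_rate per Ma).  At every speciation event inside a sympatric-mode
    clade the daughters receive opposite shifts of magnitude
    kappa * sqrt(bm_rate) on one random trait axis — the adaptive
    divergence accompanying speciation in sympatry.  Means are
    exponentiated to mm and specimens drawn with mean-preserving lognormal
    noise of coefficient of variation measurement_cv.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = len(TRAIT_NAMES)
    L = _bm_chol(config) if config.bm_rate > 0 else np.zeros((p, p))
    base = np.log(np.array(BASE_TRAIT_MEANS_MM))
    kappa_shift = config.sympatric_divergence_boost * math.sqrt(config.bm_rate)
    species_logmeans: dict[str, np.ndarray] = {}

    def descend(node: Node, logmean: np.ndarray, mode: str) -> None:
        if node.is_tip:
            species_logmeans[node.label] = logmean
            return
        shifts = [np.zeros(p), np.zeros(p)]
        if mode == "sympatric" and kappa_shift > 0:
            axis = int(rng.integers(p))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shifts[0][axis] = sign * kappa_shift
            shifts[1][axis] = -sign * kappa_shift
        for child, shift in zip(node.children, shifts):
            bl = max(node.age - child.age, 0.0)
            step = L @ rng.standard_normal(p) * math.sqrt(bl)
            descend(child, logmean + shift + step, mode)

    root = tree.root
    for child, clade in zip(root.children, ("A", "B")):
        bl = max(root.age - child.age, 0.0)
        step = L @ rng.standard_normal(p) * math.sqrt(bl)
        descend(child, base + step, config.range_mode[clade])

    cv = config.measurement_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    out: list[SpecimenRecord] = []
    for sp in sorted(species_logmeans):
        means_mm = np.exp(species_logmeans[sp])
        for i in range(config.specimens_per_species):
            noise = (
                np.exp(rng.standard_normal(p) * sigma - 0.5 * sigma * sigma)
                if sigma > 0
                else np.ones(p)
            )
            vals = means_mm * noise
            out.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_s{i + 1}",
                    species_id=sp,
                    **dict(zip(TRAIT_NAMES, (float(v) for v in vals))),
                )
            )
    return out


# ---------------------------------------------------------------------------
# composition


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Compose tree, ranges, localities, specimens and clade labels."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    ranges = simulate_ranges(tree, config, rng)
    localities: list[PointLocality] = []
    for sp in sorted(ranges):
        localities.extend(sample_localities(ranges[sp], sp, config, rng))
    specimens = simulate_traits_and_specimens(tree, config, rng)
    clades = clade_assignment(tree)
    return SyntheticDataset(
        tree=tree,
        true_ranges=ranges,
        localities=localities,
        specimens=specimens,
        clades=clades,
        provenance={"config": config.to_dict(), "seed": config.seed},
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write tree.nwk, localities.csv, specimens.csv, clades.csv, config.json.

    Output is byte-identical for identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "localities": outdir / "localities.csv",
        "specimens": outdir / "specimens.csv",
        "clades": outdir / "clades.csv",
        "config": outdir / "config.json",
    }
    ds.tree.write(paths["tree"])
    with open(paths["localities"], "w", newline="") as fh:
        fh.write("species,longitude,latitude,precision_m,source\n")
        for loc in ds.localities:
            fh.write(
                f"{loc.species_id},{loc.longitude:.8f},{loc.latitude:.8f},"
                f"{loc.precision_radius_m:.1f},{loc.source}\n"
            )
    with open(paths["specimens"], "w", newline="") as fh:
        fh.write("specimen,species," + ",".join(TRAIT_NAMES) + "\n")
        for s in ds.specimens:
            vals = ",".join(f"{v:.6f}" for v in s.values())
            fh.write(f"{s.specimen_id},{s.species_id},{vals}\n")
    with open(paths["clades"], "w", newline="") as fh:
        fh.write("species,clade\n")
        for sp in sorted(ds.clades.mapping):
            fh.write(f"{sp},{ds.clades.mapping[sp]}\n")
    with open(paths["config"], "w") as fh:
        json.dump(ds.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
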