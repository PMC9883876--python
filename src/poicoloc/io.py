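"""Readers, writers, district reporting and run configuration.

File formats are deliberately plain: CSV point tables (``id,x,y,category``),
GeoJSON FeatureCollections of Point features, an ESRI-ASCII raster for
density surfaces, and CSV/text report tables.  Geographic (lon/lat) input is
projected to planar metres on read — the statistics modules only ever see
Euclidean coordinates.  Every writer stamps the run's seed and a hash of its
configuration so outputs are traceable to the exact run that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .gclq import GCLQResult, MonteCarloConfig, significance_label
from .kde import KDESurface
from .lclq import LCLQResult
from .nni import NNIResult
from .pattern import CategoricalPointPattern, PointRecord, build_pattern

logger = logging.getLogger("poicoloc")

EARTH_RADIUS_M = 6_371_008.8


# -- projection -----------------------------------------------------------


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray,
    lon0: float | None = None, lat0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic coordinates to planar metres.

    A local equirectangular projection about the data centroid: accurate to
    well under 1% over city-scale extents, which is all the Euclidean
    statistics here require.  Returns (x, y) in metres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(lon.mean())
    if lat0 is None:
        lat0 = float(lat.mean())
    x = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings shared by the CLI subcommands."""

    input_path: str | None = None
    category_field: str = "category"
    crs: Literal["planar", "lonlat"] = "planar"
    k: int = 1
    k_max: int = 10
    monte_carlo: MonteCarloConfig = field(
        default_factory=lambda: MonteCarloConfig(n_permutations=1000, seed=0)
    )
    output_dir: str = "."
    log_level: str = "INFO"

    @property
    def seed(self) -> int | None:
        return self.monte_carlo.seed

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "input": self.input_path, "category_field": self.category_field,
                "crs": self.crs, "k": self.k, "k_max": self.k_max,
                "n_permutations": self.monte_carlo.n_permutations,
                "seed": self.monte_carlo.seed,
                "alternative": self.monte_carlo.alternative,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(config: RunConfig | None) -> str:
    if config is None:
        return "# poicoloc output"
    return f"# poicoloc seed={config.seed} config={config.config_hash()}"


# -- readers --------------------------------------------------------------


def read_points(
    path: str | Path,
    fmt: Literal["csv", "geojson"] | None = None,
    category_field: str = "category",
    crs: Literal["planar", "lonlat"] = "planar",
    region: BaseGeometry | tuple | None = None,
    area: float | None = None,
    containment: Literal["strict", "warn", "ignore"] = "warn",
) -> CategoricalPointPattern:
    """Read a categorical point pattern from CSV or GeoJSON.

    CSV needs columns ``id, x, y`` plus the category column; GeoJSON needs
    Point features carrying the category property (non-Point features are
    rejected with a warning).  With ``crs="lonlat"`` the coordinates are
    projected to planar metres before anything else happens.  If no region
    is supplied, the pattern's bounding box is used (its area is then the
    box area).
    """
    path = Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"

    if fmt == "csv":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        required = {"id", "x", "y", category_field}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        ids = df["id"].tolist()
        xs = df["x"].to_numpy(float)
        ys = df["y"].to_numpy(float)
        cats = df[category_field].astype(str).tolist()
    else:
        data = json.loads(path.read_text())
        feats = data.get("features", [])
        ids, xs_l, ys_l, cats = [], [], [], []
        for i, f in enumerate(feats):
            geom = f.get("geometry") or {}
            if geom.get("type") != "Point":
                logger.warning("%s: feature %d is %s, not Point; rejected",
                               path, i, geom.get("type"))
                continue
            props = f.get("properties") or {}
            if category_field not in props:
                raise ValueError(f"{path}: feature {i} lacks {category_field!r}")
            x, y = geom["coordinates"][:2]
            ids.append(props.get("id", f.get("id", i)))
            xs_l.append(float(x))
            ys_l.append(float(y))
            cats.append(str(props[category_field]))
        xs, ys = np.asarray(xs_l), np.asarray(ys_l)
    if len(ids) == 0:
        raise ValueError(f"{path}: no usable point records")

    if crs == "lonlat":
        xs, ys = project_lonlat(xs, ys)
        logger.info("projected %d lon/lat points to local planar metres", len(ids))

    records = [PointRecord(i, float(x), float(y), c)
               for i, x, y, c in zip(ids, xs, ys, cats)]
    if region is None:
        # bounding box; pad degenerate extents (e.g. collinear points) so the
        # implied area stays positive
        w = float(xs.max() - xs.min())
        h = float(ys.max() - ys.min())
        pad = 0.5 * max(w, h, 1.0) * 1e-6 if min(w, h) > 0 else 0.5 * max(w, h, 1.0)
        padx = pad if w == 0 else 0.0
        pady = pad if h == 0 else 0.0
        region = (float(xs.min()) - padx, float(ys.min()) - pady,
                  float(xs.max()) + padx, float(ys.max()) + pady)
    return build_pattern(records, region=region, area=area, containment=containment)


# -- writers --------------------------------------------------------------


def write_points_csv(
    pattern: CategoricalPointPattern, path: str | Path,
    config: RunConfig | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        fh.write("id,x,y,category\n")
        for pid, (x, y), c in zip(pattern.ids, pattern.coords, pattern.categories):
            fh.write(f"{pid},{float(x)!r},{float(y)!r},{c}\n")


def write_nni_table(
    results: Sequence[NNIResult], path: str | Path, config: RunConfig | None = None
) -> None:
    """One row per category: NNI, Z score, p — the standard agglomeration table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        fh.write("category,n,NNI,Z,p\n")
        for r in results:
            fh.write(f"{r.category},{r.n},{r.nni:.6f},{r.z:.4f},{r.p_value:.6g}\n")


def format_gclq_cell(k: int, value: float, p: float | None) -> str:
    """Matrix cell text ``k(value)stars``, e.g. ``1(2.279)***``."""
    stars = significance_label(p)
    return f"{k}({value:.3f})" + ("" if stars == "ns" else stars)


def write_gclq_matrix(
    tidy: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write both views of a GCLQ matrix: the compact ``k(value)stars`` grid
    (rows = A categories, columns = B categories) and, alongside it with a
    ``_long.csv`` suffix, the tidy per-pair table."""
    path = Path(path)
    cats = sorted(set(tidy["a_category"]) | set(tidy["b_category"]))
    grid = pd.DataFrame(index=cats, columns=cats, dtype=object)
    for _, row in tidy.iterrows():
        grid.loc[row["a_category"], row["b_category"]] = format_gclq_cell(
            int(row["k"]), row["value"], row["p"]
        )
    with path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        grid.index.name = "category"
        grid.to_csv(fh)
    long_path = path.with_name(path.stem + "_long.csv")
    with long_path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        tidy.to_csv(fh, index=False)


def lclq_to_geojson(
    results: Sequence[LCLQResult],
    pattern: CategoricalPointPattern,
    config: RunConfig | None = None,
) -> dict:
    """Per-point LCLQ layer as a GeoJSON FeatureCollection (possibly empty)."""
    features = []
    for r in results:
        i = pattern.index_of(r.focal_id)
        x, y = pattern.coords[i]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {
                    "id": r.focal_id if not isinstance(r.focal_id, np.generic)
                    else r.focal_id.item(),
                    "a_category": r.a_category,
                    "b_category": r.b_category,
                    "value": r.value,
                    "p_value": r.p_value,
                },
            }
        )
    meta = {}
    if config is not None:
        meta = {"seed": config.seed, "config": config.config_hash()}
    return {"type": "FeatureCollection", "metadata": meta, "features": features}


def write_lclq(
    results: Sequence[LCLQResult],
    pattern: CategoricalPointPattern,
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Write an LCLQ result set as GeoJSON (.geojson/.json) or tidy CSV."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        path.write_text(json.dumps(lclq_to_geojson(results, pattern, config), indent=1))
        return
    with path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        fh.write("id,x,y,a_category,b_category,bandwidth,share,value,p\n")
        for r in results:
            i = pattern.index_of(r.focal_id)
            x, y = pattern.coords[i]
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.focal_id},{float(x)!r},{float(y)!r},{r.a_category},{r.b_category},"
                f"{r.bandwidth_distance:.6g},{r.weighted_b_share:.6g},"
                f"{r.value:.6g},{p}\n"
            )


def write_kde_ascii(surface: KDESurface, path: str | Path) -> None:
    """ESRI ASCII grid (north-up row order) of a density surface."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {surface.n_cols}\n")
        fh.write(f"nrows {surface.n_rows}\n")
        fh.write(f"xllcorner {surface.origin[0]!r}\n")
        fh.write(f"yllcorner {surface.origin[1]!r}\n")
        fh.write(f"cellsize {surface.cell_size!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in surface.values[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_kde_ascii(path: str | Path) -> KDESurface:
    """Round-trip reader for :func:`write_kde_ascii` (bandwidth not stored)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    for ln in lines[:6]:
        key, val = ln.split(None, 1)
        header[key.lower()] = val
    values = np.array(
        [[float(v) for v in ln.split()] for ln in lines[6:]], dtype=float
    )[::-1]
    return KDESurface(
        origin=(float(header["xllcorner"]), float(header["yllcorner"])),
        cell_size=float(header["cellsize"]),
        n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
        values=values, bandwidth=float("nan"),
    )


# -- district reporting ---------------------------------------------------


@dataclass(frozen=True)
class DistrictSummary:
    """Per-district medical-resource provision: counts and the two equity
    rates (count per unit area, count per capita)."""

    district_id: object
    area: float
    population: int
    counts: dict
    count_per_area: dict
    count_per_capita: dict
    count_per_capita_per_area: dict

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def district_summary(
    pattern: CategoricalPointPattern,
    districts: Sequence[dict],
) -> list[DistrictSummary]:
    """Per-category counts and provision rates for each district polygon.

    ``districts`` is a sequence of mappings with keys ``id``, ``polygon``
    (shapely geometry), ``population`` and optionally ``area`` (defaults to
    the polygon's geometric area).  Each point is assigned to the first
    district in input order whose polygon covers it, so a point on a shared
    boundary is counted exactly once.  Overlapping districts draw a warning.
    Both the per-area and per-capita rate are reported, plus their
    combination count/(population x area).
    """
    import shapely

    for i in range(len(districts)):
        for j in range(i + 1, len(districts)):
            inter = districts[i]["polygon"].intersection(districts[j]["polygon"])
            if inter.area > 0:
                logger.warning(
                    "districts %r and %r overlap (area %g)",
                    districts[i]["id"], districts[j]["id"], inter.area,
                )

    cats = sorted(pattern.category_set)
    pts = shapely.points(pattern.coords)
    assigned = np.full(pattern.n, -1)
    for d_idx, d in enumerate(districts):
        free = assigned < 0
        covered = shapely.covers(d["polygon"], pts[free])
        assigned[np.flatnonzero(free)[covered]] = d_idx

    out = []
    for d_idx, d in enumerate(districts):
        area = float(d.get("area") or d["polygon"].area)
        population = int(d["population"])
        if area <= 0 or population <= 0:
            raise ValueError(f"district {d['id']!r}: area and population must be > 0")
        in_d = assigned == d_idx
        counts = {
            c: int(((pattern.categories == c) & in_d).sum()) for c in cats
        }
        out.append(
            DistrictSummary(
                district_id=d["id"], area=area, population=population,
                counts=counts,
                count_per_area={c: n / area for c, n in counts.items()},
                count_per_capita={c: n / population for c, n in counts.items()},
                count_per_capita_per_area={
                    c: n / (population * area) for c, n in counts.items()
                },
            )
        )
    return out


def write_district_summary(
    summaries: Sequence[DistrictSummary], path: str | Path,
    config: RunConfig | None = None,
) -> None:
    path = Path(path)
    cats = sorted({c for s in summaries for c in s.counts})
    with path.open("w") as fh:
        fh.write(_stamp(config) + "\n")
        head = ["district", "area", "population"]
        for c in cats:
            head += [f"{c}_count", f"{c}_per_area", f"{c}_per_capita"]
        fh.write(",".join(head) + "\n")
        for s in summaries:
            row = [str(s.district_id), f"{s.area:.6g}", str(s.population)]
            for c in cats:
                row += [
                    str(s.counts[c]),
                    f"{s.count_per_area[c]:.6g}",
                    f"{s.count_per_capita[c]:.6g}",
                ]
            fh.write(",".join(row) + "\n")
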