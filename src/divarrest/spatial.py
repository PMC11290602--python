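"""Presence-absence rasterization and per-quantile richness grids.

Ranges are rasterized onto the global geographic 1-degree lattice (origin at
the south-west corner, longitude [-180, 180), latitude [-90, 90), cells
half-open in both axes).  A family is present in a cell when any of its
geometries intersects the cell's open interior — the conservative choice for
narrow ranges at this resolution; a "centre-within" rule is available for
sensitivity checks.  Per-quantile richness grids are column sums of the
presence matrix over the quantile's families, so summing the grids of all
quantiles reproduces the all-family richness grid cell by cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.validation import make_valid

from .errors import ConfigurationError, MappingError

log = logging.getLogger(__name__)

LON_MIN, LON_MAX = -180.0, 180.0
LAT_MIN, LAT_MAX = -90.0, 90.0
DEFAULT_RESOLUTION = 1.0


# ---------------------------------------------------------------------------
# RangeSet
# ---------------------------------------------------------------------------


@dataclass
class RangeSet:
    """Per-family geometries in geographic coordinates."""

    geometries: dict[str, list]  # family -> list of shapely geometries

    @property
    def families(self) -> list[str]:
        return sorted(self.geometries)


def _split_antimeridian_box(lon_min, lon_max, lat_min, lat_max):
    """Boxes stated with lon_min > lon_max wrap across the antimeridian."""
    if lon_min <= lon_max:
        return [box(lon_min, lat_min, lon_max, lat_max)]
    return [
        box(lon_min, lat_min, LON_MAX, lat_max),
        box(LON_MIN, lat_min, lon_max, lat_max),
    ]


def read_bbox_csv(path: str | Path) -> RangeSet:
    """Read per-family bounding boxes: family,lon_min,lon_max,lat_min,lat_max."""
    df = pd.read_csv(path)
    required = {"family", "lon_min", "lon_max", "lat_min", "lat_max"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: bounding-box CSV needs columns {sorted(required)}"
        )
    geoms: dict[str, list] = {}
    for row in df.itertuples(index=False):
        if not (LAT_MIN <= row.lat_min <= row.lat_max <= LAT_MAX):
            raise ConfigurationError(f"latitude bounds out of range for {row.family}")
        geoms.setdefault(str(row.family), []).extend(
            _split_antimeridian_box(row.lon_min, row.lon_max,
                                    row.lat_min, row.lat_max)
        )
    return RangeSet(geometries=geoms)


def read_geojson(path: str | Path) -> RangeSet:
    """Read a GeoJSON FeatureCollection; feature property 'family' keys ranges."""
    data = json.loads(Path(path).read_text())
    geoms: dict[str, list] = {}
    for feat in data.get("features", []):
        fam = feat.get("properties", {}).get("family")
        if fam is None:
            raise MappingError("GeoJSON feature lacks a 'family' property")
        geoms.setdefault(str(fam), []).append(shape(feat["geometry"]))
    return RangeSet(geometries=geoms)


# ---------------------------------------------------------------------------
# Presence-absence
# ---------------------------------------------------------------------------


@dataclass
class PresenceAbsence:
    """Binary families x grid matrix at a fixed resolution.

    ``matrix`` has shape (n_families, n_lat, n_lon) with cell [j, i]
    spanning [lon_i, lon_i + res) x [lat_j, lat_j + res), origin at
    (-180, -90).
    """

    families: list[str]
    matrix: np.ndarray = field(repr=False)
    resolution: float = DEFAULT_RESOLUTION

    def row(self, family: str) -> np.ndarray:
        try:
            return self.matrix[self.families.index(family)]
        except ValueError:
            raise KeyError(f"family {family!r} not in presence matrix") from None


def _grid_shape(resolution: float) -> tuple[int, int]:
    n_lon = int(round((LON_MAX - LON_MIN) / resolution))
    n_lat = int(round((LAT_MAX - LAT_MIN) / resolution))
    if abs(n_lon * resolution - 360.0) > 1e-9 or abs(n_lat * resolution - 180.0) > 1e-9:
        raise ConfigurationError("resolution must divide 360 and 180 evenly")
    return n_lat, n_lon


def _rasterize(geom, resolution: float, rule: str, out: np.ndarray) -> None:
    """OR the cells hit by ``geom`` into boolean plane ``out`` (n_lat, n_lon)."""
    n_lat, n_lon = out.shape
    gxmin, gymin, gxmax, gymax = geom.bounds
    i0 = max(int(np.floor((gxmin - LON_MIN) / resolution)), 0)
    i1 = min(int(np.ceil((gxmax - LON_MIN) / resolution)), n_lon)
    j0 = max(int(np.floor((gymin - LAT_MIN) / resolution)), 0)
    j1 = min(int(np.ceil((gymax - LAT_MIN) / resolution)), n_lat)
    if rule == "centre":
        lons = LON_MIN + (np.arange(i0, i1) + 0.5) * resolution
        lats = LAT_MIN + (np.arange(j0, j1) + 0.5) * resolution
        from shapely import points, contains

        for jj, lat in zip(range(j0, j1), lats):
            pts = points(np.column_stack([lons, np.full_like(lons, lat)]))
            out[jj, i0:i1] |= contains(geom, pts)
        return
    if rule != "intersects":
        raise ConfigurationError(f"unknown presence rule {rule!r}")
    # fast path: axis-aligned rectangles reduce to index arithmetic under the
    # open-interior rule (box interior must overlap cell interior)
    if geom.geom_type == "Polygon" and _is_rectangle(geom):
        if gxmax > gxmin and gymax > gymin:
            ia = int(np.floor((gxmin - LON_MIN) / resolution))
            ib = int(np.ceil((gxmax - LON_MIN) / resolution))
            ja = int(np.floor((gymin - LAT_MIN) / resolution))
            jb = int(np.ceil((gymax - LAT_MIN) / resolution))
            out[max(ja, 0):min(jb, n_lat), max(ia, 0):min(ib, n_lon)] = True
        return
    for j in range(j0, j1):
        for i in range(i0, i1):
            cell = box(LON_MIN + i * resolution, LAT_MIN + j * resolution,
                       LON_MIN + (i + 1) * resolution,
                       LAT_MIN + (j + 1) * resolution)
            # interior/interior intersection: overlap beyond a shared boundary
            if geom.relate(cell)[0] in "012":
                out[j, i] = True


def _is_rectangle(poly) -> bool:
    return poly.equals(box(*poly.bounds))


def presence_absence(
    range_set: RangeSet,
    resolution: float = DEFAULT_RESOLUTION,
    rule: str = "intersects",
) -> PresenceAbsence:
    """Rasterize every family's ranges onto the global grid.

    ``rule='intersects'`` marks a cell when the geometry overlaps its open
    interior; ``rule='centre'`` requires the cell centre to fall inside
    the geometry.  Invalid geometries are repaired with ``make_valid``;
    families whose geometries stay invalid are excluded with a warning.
    """
    n_lat, n_lon = _grid_shape(resolution)
    families = range_set.families
    kept, planes = [], []
    for fam in families:
        plane = np.zeros((n_lat, n_lon), dtype=bool)
        ok = True
        for geom in range_set.geometries[fam]:
            if not geom.is_valid:
                geom = make_valid(geom)
                if not geom.is_valid:
                    log.warning("family %s: invalid geometry after repair; "
                                "excluding family", fam)
                    ok = False
                    break
            xmin, ymin, xmax, ymax = geom.bounds
            if xmin < LON_MIN - 1e-9 or xmax > LON_MAX + 1e-9 \
                    or ymin < LAT_MIN - 1e-9 or ymax > LAT_MAX + 1e-9:
                log.warning("family %s: geometry out of bounds; excluding", fam)
                ok = False
                break
            _rasterize(geom, resolution, rule, plane)
        if ok:
            kept.append(fam)
            planes.append(plane)
    matrix = (np.stack(planes) if planes
              else np.zeros((0, n_lat, n_lon), dtype=bool))
    return PresenceAbsence(families=kept, matrix=matrix, resolution=resolution)


# ---------------------------------------------------------------------------
# Richness grids
# ---------------------------------------------------------------------------


@dataclass
class RichnessGrid:
    """Per-cell family counts on the geographic lattice."""

    values: np.ndarray  # (n_lat, n_lon) non-negative ints
    resolution: float = DEFAULT_RESOLUTION

    def to_frame(self) -> pd.DataFrame:
        """Long-format lon,lat,count table (cell south-west corners)."""
        n_lat, n_lon = self.values.shape
        lon = LON_MIN + np.arange(n_lon) * self.resolution
        lat = LAT_MIN + np.arange(n_lat) * self.resolution
        jj, ii = np.nonzero(self.values)
        return pd.DataFrame({
            "lon": lon[ii], "lat": lat[jj],
            "count": self.values[jj, ii].astype(int),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def richness_map(pam: PresenceAbsence, family_subset=None) -> RichnessGrid:
    """Per-cell count of present families over a subset (default: all)."""
    if family_subset is None:
        rows = np.arange(len(pam.families))
    else:
        unknown = [f for f in family_subset if f not in pam.families]
        if unknown:
            raise KeyError(f"families not in presence matrix: {unknown[:10]}")
        pos = {f: i for i, f in enumerate(pam.families)}
        rows = np.array([pos[f] for f in family_subset], dtype=np.intp)
    values = pam.matrix[rows].sum(axis=0).astype(np.int64)
    return RichnessGrid(values=values, resolution=pam.resolution)


def quantile_maps(
    pam: PresenceAbsence, rate_table: pd.DataFrame
) -> dict[int, RichnessGrid]:
    """One richness grid per diversification quantile.

    Families with a quantile but no usable geometry are logged and
    skipped; an empty quantile yields an all-zero grid with a warning.
    """
    grids: dict[int, RichnessGrid] = {}
    for q, group in rate_table.groupby("quantile", sort=True):
        fams = [f for f in group["family"] if f in pam.families]
        skipped = sorted(set(group["family"]) - set(fams))
        if skipped:
            log.warning("quantile %s: no geometries for %d families (%s...)",
                        q, len(skipped), skipped[:3])
        if not fams:
            log.warning("quantile %s has no mapped families; emitting empty grid", q)
            grids[int(q)] = RichnessGrid(
                values=np.zeros(pam.matrix.shape[1:], dtype=np.int64),
                resolution=pam.resolution,
            )
        else:
            grids[int(q)] = richness_map(pam, fams)
    return grids


def plot_quantile_maps(grids: dict[int, RichnessGrid], title: str = ""):
    """Render per-quantile richness maps with a perceptually uniform palette."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    k = len(grids)
    fig, axes = plt.subplots(k, 1, figsize=(8, 3 * k), squeeze=False)
    vmax = max(int(g.values.max()) for g in grids.values()) or 1
    for ax, (q, grid) in zip(axes.ravel(), sorted(grids.items())):
        im = ax.imshow(
            grid.values, origin="lower", cmap="viridis", vmin=0, vmax=vmax,
            extent=[LON_MIN, LON_MAX, LAT_MIN, LAT_MAX], aspect="auto",
        )
        ax.set_title(f"quantile {q}")
        fig.colorbar(im, ax=ax, shrink=0.8, label="families")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
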