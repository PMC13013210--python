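"""Population exposure to thermal-stress classes.

Overlays a classified SSI raster with population-bearing polygons and
distributes each zone's residents across comfort categories in
proportion to covered area (areal weighting — the standard assumption
when no finer population surface exists). Cell membership uses a
cell-center-in-polygon test; integer counts come from largest-remainder
rounding so every table conserves the input population exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .grid import CategoricalGrid, class_area_fractions, EmptyDomainError

__all__ = [
    "ZonePolygon",
    "UNCLASSIFIED_CODE",
    "zone_category_shares",
    "apportion_population",
    "aggregate_exposure",
    "load_zones_geojson",
]

#: bucket for zones with no valid raster coverage
UNCLASSIFIED_CODE = -1


@dataclass(frozen=True)
class ZonePolygon:
    """A population-bearing polygon in the same CRS as the raster."""

    zone_id: str
    geometry: BaseGeometry
    population: int
    crs: str = "unspecified"

    def __post_init__(self):
        if self.population < 0:
            raise ValueError(f"zone {self.zone_id!r}: population must be nonnegative")
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"zone {self.zone_id!r}: invalid or empty geometry")


def _zone_mask(cat: CategoricalGrid, geometry: BaseGeometry) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the polygon."""
    x0, px, _, y0, _, py = cat.transform
    rows, cols = cat.shape
    # restrict the test to the geometry's bounding box
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(int(np.floor((minx - x0) / px)), 0)
    c1 = min(int(np.ceil((maxx - x0) / px)) + 1, cols)
    r0 = max(int(np.floor((maxy - y0) / py)), 0)
    r1 = min(int(np.ceil((miny - y0) / py)) + 1, rows)
    mask = np.zeros((rows, cols), dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    xs = x0 + (np.arange(c0, c1) + 0.5) * px
    ys = y0 + (np.arange(r0, r1) + 0.5) * py
    gx, gy = np.meshgrid(xs, ys)
    mask[r0:r1, c0:c1] = shapely.contains_xy(geometry, gx, gy)
    return mask


def zone_category_shares(cat: CategoricalGrid, zone: ZonePolygon) -> dict[int, float]:
    """Fraction of the zone's valid-cell area in each category.

    Returns an empty dict (zero-coverage) when the zone misses the grid
    or covers only nodata.
    """
    if zone.crs != cat.crs:
        raise ValueError(f"CRS mismatch: zone {zone.crs!r} vs raster {cat.crs!r}")
    mask = _zone_mask(cat, zone.geometry)
    try:
        pct = class_area_fractions(cat, mask=mask)
    except EmptyDomainError:
        return {}
    return {code: p / 100.0 for code, p in pct.items()}


def apportion_population(shares: dict[int, float], population: int) -> dict[int, int]:
    """Integer persons per category via largest-remainder rounding.

    The rounded counts sum exactly to ``population``; ties break by
    ascending category code so tables are reproducible bit-for-bit.
    Zero-coverage (empty shares) puts everyone in the unclassified bucket.
    """
    if population < 0:
        raise ValueError("population must be nonnegative")
    if not shares:
        return {UNCLASSIFIED_CODE: population}
    codes = sorted(shares)
    raw = np.array([shares[c] * population for c in codes])
    base = np.floor(raw).astype(int)
    shortfall = int(round(population - base.sum()))
    remainders = raw - base
    # stable: largest remainder first, then ascending code
    order = sorted(range(len(codes)), key=lambda i: (-remainders[i], codes[i]))
    for i in order[:shortfall]:
        base[i] += 1
    return dict(zip(codes, base.tolist()))


def aggregate_exposure(
    cat: CategoricalGrid, zones: list[ZonePolygon]
) -> pd.DataFrame:
    """Per-category population and area shares across all zones.

    Columns: code, label, population, population_pct, area_pct. The
    area percentages are computed over the union of zone footprints;
    population percentages over the summed zone populations. Both sum
    to 100 (population conservation is exact by construction).
    """
    if not zones:
        raise ValueError("need at least one zone")
    for z in zones:
        if z.crs != cat.crs:
            raise ValueError(f"CRS mismatch: zone {z.zone_id!r} is {z.crs!r}, raster {cat.crs!r}")

    pop_by_code: dict[int, int] = {}
    union_mask = np.zeros(cat.shape, dtype=bool)
    for z in zones:
        union_mask |= _zone_mask(cat, z.geometry)
        for code, persons in apportion_population(
            zone_category_shares(cat, z), z.population
        ).items():
            pop_by_code[code] = pop_by_code.get(code, 0) + persons

    try:
        area_pct = class_area_fractions(cat, mask=union_mask)
    except EmptyDomainError:
        area_pct = {}

    total_pop = sum(z.population for z in zones)
    codes = sorted(set(pop_by_code) | set(area_pct))
    rows = []
    for code in codes:
        if code == UNCLASSIFIED_CODE:
            label = "Unclassified"
        else:
            label = cat.scheme.by_code(code).label
        pop = pop_by_code.get(code, 0)
        rows.append({
            "code": code,
            "label": label,
            "population": pop,
            "population_pct": 100.0 * pop / total_pop if total_pop else 0.0,
            "area_pct": area_pct.get(code, 0.0),
        })
    return pd.DataFrame(rows)


def load_zones_geojson(
    path,
    id_field: str = "zone_id",
    population_field: str = "population",
    crs: str | None = None,
) -> list[ZonePolygon]:
    """Read zones from a GeoJSON FeatureCollection.

    The CRS is taken from a top-level ``crs`` name member if present,
    overridable via the ``crs`` argument (GeoJSON is nominally WGS84 but
    this toolkit works in projected coordinates).
    """
    with open(path) as fh:
        payload = json.load(fh)
    if crs is None:
        crs = (payload.get("crs", {}).get("properties", {}) or {}).get("name", "unspecified")
    zones = []
    for feat in payload["features"]:
        props = feat.get("properties", {})
        try:
            zones.append(ZonePolygon(
                zone_id=str(props[id_field]),
                geometry=shapely_shape(feat["geometry"]),
                population=int(props[population_field]),
                crs=crs,
            ))
        except KeyError as exc:
            raise ValueError(f"zone feature missing field {exc}") from exc
    return zones


def zones_to_geojson(zones: list[ZonePolygon], path) -> None:
    """Write zones as a GeoJSON FeatureCollection with a crs name member."""
    from shapely.geometry import mapping

    payload = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": zones[0].crs if zones else "unspecified"}},
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(z.geometry),
                "properties": {"zone_id": z.zone_id, "population": z.population},
            }
            for z in zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
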