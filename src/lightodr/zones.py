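"""Zone polygons and zonal statistics of nighttime-light brightness.

Zones are administrative units (provinces or cities) as shapely polygons with
stable identifiers, read from / written to GeoJSON. The zonal reduction
implements the two brightness summaries the prediction model consumes:

    SUM  = sum of DN over a zone's effective pixels
    MEAN = SUM / n,  n the number of effective pixels

An *effective pixel* is any non-nodata cell whose center falls inside the
zone polygon — zero-DN cells included, so MEAN stays well defined for dark
zones. Cells lying exactly on a shared boundary are assigned to exactly one
zone: the first in zone-ID-sorted order, a deterministic rule independent of
input file ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .raster import LightRaster

logger = logging.getLogger(__name__)

__all__ = [
    "ZonePolygons",
    "ZonalStatistics",
    "read_zones_geojson",
    "write_zones_geojson",
    "mask_extract",
    "zonal_stats",
    "zonal_stats_frame",
    "write_zonal_stats_csv",
]

LEVELS = ("province", "city")


@dataclass
class ZonePolygons:
    """A set of zone polygons at one nesting level.

    ``zone_ids`` are unique text identifiers; ``geometries`` shapely
    (multi)polygons in the raster coordinate frame; ``level`` is
    ``"province"`` or ``"city"``.
    """

    zone_ids: list
    geometries: list
    level: str = "city"

    def __post_init__(self):
        self.zone_ids = [str(z) for z in self.zone_ids]
        if len(self.zone_ids) != len(self.geometries):
            raise ValueError("zone_ids and geometries differ in length")
        if len(set(self.zone_ids)) != len(self.zone_ids):
            raise ValueError("zone_id values must be unique within a level")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        for zid, geom in zip(self.zone_ids, self.geometries):
            if geom.is_empty or geom.area <= 0:
                raise ValueError(f"zone {zid!r} has empty or zero-area geometry")

    def __len__(self):
        return len(self.zone_ids)

    def __iter__(self):
        return iter(zip(self.zone_ids, self.geometries))


def read_zones_geojson(path, zone_id_field="zone_id", level="city") -> ZonePolygons:
    """Read zone polygons from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    ids, geoms = [], []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if zone_id_field not in props:
            raise ValueError(f"feature missing id field {zone_id_field!r}")
        ids.append(str(props[zone_id_field]))
        geoms.append(shape(feat["geometry"]))
    return ZonePolygons(ids, geoms, level=level)


def write_zones_geojson(zones: ZonePolygons, path, zone_id_field="zone_id"):
    feats = [
        {
            "type": "Feature",
            "properties": {zone_id_field: zid, "level": zones.level},
            "geometry": mapping(geom),
        }
        for zid, geom in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def mask_extract(raster: LightRaster, zones: ZonePolygons) -> dict:
    """Assign raster cells to zones by the cell-center point-in-polygon test.

    Returns ``{zone_id: ndarray of flat cell indices}``. Nodata cells are
    never assigned. Boundary cells (centers exactly on a polygon boundary)
    go to the first zone in ID-sorted order. Zones wholly outside the raster
    extent come back with an empty index set and a logged warning.
    """
    xs, ys = raster.cell_centers()
    flat_x = xs.ravel()
    flat_y = ys.ravel()
    usable = ~raster.nodata_mask.ravel()
    assigned = np.zeros(flat_x.size, dtype=bool)

    out = {}
    order = sorted(range(len(zones)), key=lambda i: zones.zone_ids[i])
    for i in order:
        zid = zones.zone_ids[i]
        geom = zones.geometries[i]
        minx, miny, maxx, maxy = geom.bounds
        cand = np.flatnonzero(
            usable & ~assigned
            & (flat_x >= minx) & (flat_x <= maxx)
            & (flat_y >= miny) & (flat_y <= maxy)
        )
        if cand.size:
            # intersects on points == covers: boundary centers count
            hit = shapely.intersects_xy(geom, flat_x[cand], flat_y[cand])
            cells = cand[hit]
        else:
            cells = np.empty(0, dtype=np.int64)
        if cells.size == 0:
            logger.warning("zone %s has no effective pixels in the raster extent", zid)
        assigned[cells] = True
        out[zid] = cells
    # restore input zone order for readability
    return {zid: out[zid] for zid in zones.zone_ids}


@dataclass
class ZonalStatistics:
    """SUM of DN, MEAN of DN and effective-pixel count for one zone."""

    zone_id: str
    sum_dn: float
    mean_dn: float
    n_pixels: int


def zonal_stats(raster: LightRaster, cells: dict) -> list:
    """Reduce a cell assignment to per-zone SUM, MEAN and pixel count.

    Zones with zero effective pixels are omitted (and logged). Sums over
    integer rasters are exact integer arithmetic.
    """
    flat = raster.values.ravel()
    nodata = raster.nodata_mask.ravel()
    results = []
    for zid, idx in cells.items():
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            logger.warning("zone %s omitted from zonal statistics (no pixels)", zid)
            continue
        if idx.min() < 0 or idx.max() >= flat.size:
            raise IndexError(f"zone {zid!r} references out-of-range cells")
        if nodata[idx].any():
            raise ValueError(f"zone {zid!r} references nodata cells")
        vals = flat[idx]
        if np.issubdtype(vals.dtype, np.integer):
            total = int(vals.sum(dtype=np.int64))
        else:
            total = float(vals.sum())
        n = int(idx.size)
        results.append(ZonalStatistics(zid, total, total / n, n))
    return results


def zonal_stats_frame(stats, level="city") -> pd.DataFrame:
    """Tabulate ZonalStatistics as a DataFrame with the standard columns."""
    return pd.DataFrame(
        {
            "zone_id": [s.zone_id for s in stats],
            "level": level,
            "sum_dn": [s.sum_dn for s in stats],
            "mean_dn": [s.mean_dn for s in stats],
            "n_pixels": [s.n_pixels for s in stats],
        }
    )


def write_zonal_stats_csv(stats, path, level="city"):
    zonal_stats_frame(stats, level=level).to_csv(path, index=False)
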