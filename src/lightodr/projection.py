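"""Map projections for raster reprojection.

Only what the nighttime-light workflow needs: geographic (longitude/latitude)
coordinates and the Albers equal-area conic projection conventional for
China-extent analysis (central meridian 105°E, standard parallels 25°N/47°N).
Spherical formulas (authalic radius) are used; the sub-kilometre difference to
the ellipsoidal form is irrelevant at the 1 km grid scale this package works at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CRS", "Geographic", "AlbersEqualArea", "CHINA_ALBERS", "parse_crs"]

#: Authalic Earth radius in metres (sphere of equal area to GRS80).
EARTH_RADIUS = 6_371_007.181


class CRS:
    """Base coordinate reference system.

    Subclasses implement ``forward`` (lon/lat degrees -> projected x/y) and
    ``inverse`` (projected x/y -> lon/lat degrees), vectorised over numpy
    arrays.
    """

    label: str = "abstract"

    def forward(self, lon, lat):
        raise NotImplementedError

    def inverse(self, x, y):
        raise NotImplementedError

    def __eq__(self, other):
        return isinstance(other, CRS) and self.label == other.label

    def __hash__(self):
        return hash(self.label)


class Geographic(CRS):
    """Plain longitude/latitude in degrees (WGS-84 style graticule)."""

    label = "lonlat"

    def forward(self, lon, lat):
        return np.asarray(lon, dtype=float), np.asarray(lat, dtype=float)

    def inverse(self, x, y):
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


@dataclass(frozen=True)
class AlbersEqualArea(CRS):
    """Albers equal-area conic on a sphere.

    Parameters follow the conventional naming: ``lon0``/``lat0`` projection
    origin, ``lat1``/``lat2`` standard parallels, all in degrees.
    """

    lon0: float = 105.0
    lat0: float = 0.0
    lat1: float = 25.0
    lat2: float = 47.0
    radius: float = EARTH_RADIUS

    @property
    def label(self) -> str:  # type: ignore[override]
        return f"albers:{self.lon0}:{self.lat0}:{self.lat1}:{self.lat2}"

    def _constants(self):
        p1, p2, p0 = map(math.radians, (self.lat1, self.lat2, self.lat0))
        n = 0.5 * (math.sin(p1) + math.sin(p2))
        c = math.cos(p1) ** 2 + 2.0 * n * math.sin(p1)
        rho0 = self.radius * math.sqrt(c - 2.0 * n * math.sin(p0)) / n
        return n, c, rho0

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        n, c, rho0 = self._constants()
        rho = self.radius * np.sqrt(c - 2.0 * n * np.sin(lat)) / n
        theta = n * (lon - math.radians(self.lon0))
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, c, rho0 = self._constants()
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * (rho0 - y))
        sin_lat = (c - (rho * n / self.radius) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
        lon = self.lon0 + np.degrees(theta / n)
        return lon, lat


#: The fixed China Albers used by default throughout the package.
CHINA_ALBERS = AlbersEqualArea(lon0=105.0, lat0=0.0, lat1=25.0, lat2=47.0)


def parse_crs(spec) -> CRS:
    """Resolve a projection spec (CRS instance or text tag) to a CRS.

    Accepted tags: ``"lonlat"`` and ``"albers-china"``; anything else raises
    ``ValueError`` (a configuration error).
    """
    if isinstance(spec, CRS):
        return spec
    if isinstance(spec, str):
        tag = spec.strip().lower()
        if tag in ("lonlat", "wgs84", "epsg:4326"):
            return Geographic()
        if tag in ("albers-china", "albers_china", "china-albers"):
            return CHINA_ALBERS
    raise ValueError(f"unknown projection spec: {spec!r}")
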