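"""Gridded nighttime-light (DN) rasters: container, text I/O and resampling.

The brightness source is a single-band grid of digital numbers (DN), integers
0-63 for the DMSP/OLS annual composites, with a nodata mask and an affine
geotransform. Rasters are read and written as ESRI ASCII grids (a plain-text
single-band raster convention) since that round-trips the same information as
a single-band GeoTIFF; the coordinate reference system travels alongside as a
:class:`~lightodr.projection.CRS`.

Reprojection + resampling supports nearest, bilinear and cubic-convolution
(Keys kernel, a = -0.5) interpolation, matching the behaviour of the usual
GIS resamplers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .projection import CRS, Geographic, parse_crs

logger = logging.getLogger(__name__)

__all__ = [
    "LightRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "reproject_resample",
]

DN_MIN, DN_MAX = 0, 63
DEFAULT_NODATA = 255


@dataclass
class LightRaster:
    """A single-band brightness raster.

    Attributes
    ----------
    values : ndarray, shape (nrows, ncols)
        DN values. Integer 0-63 before resampling; cubic resampling yields
        fractional values clamped back into [0, 63].
    nodata_mask : boolean ndarray, same shape
        True where the cell carries no data.
    geotransform : 6-tuple of float
        GDAL-style (x0, dx, 0, y0, 0, dy): the top-left corner of the grid
        and the (rotation-free) cell sizes, dy < 0 for north-up grids.
    crs : CRS
        Coordinate reference system of the geotransform.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    geotransform: tuple
    crs: CRS = field(default_factory=Geographic)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask must have identical shape")
        if self.values.ndim != 2:
            raise ValueError("raster must be a 2-D grid")
        gt = tuple(float(g) for g in self.geotransform)
        if len(gt) != 6 or gt[2] != 0.0 or gt[4] != 0.0:
            raise ValueError("geotransform must be a rotation-free 6-tuple")
        if gt[1] == 0.0 or gt[5] == 0.0:
            raise ValueError("geotransform cell sizes must be nonzero")
        self.geotransform = gt

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self):
        return self.values.shape

    @property
    def crs_label(self) -> str:
        return self.crs.label

    def cell_centers(self):
        """(x, y) coordinates of every cell center, each shaped like values."""
        x0, dx, _, y0, _, dy = self.geotransform
        nrows, ncols = self.shape
        cols = np.arange(ncols) + 0.5
        rows = np.arange(nrows) + 0.5
        xs = x0 + cols * dx
        ys = y0 + rows * dy
        return np.meshgrid(xs, ys)

    def coords_to_fractional_index(self, x, y):
        """Map coordinates to fractional (row, col) pixel indices.

        Index (0, 0) is the center of the top-left cell.
        """
        x0, dx, _, y0, _, dy = self.geotransform
        col = (np.asarray(x, dtype=float) - x0) / dx - 0.5
        row = (np.asarray(y, dtype=float) - y0) / dy - 0.5
        return row, col

    # -- invariants ---------------------------------------------------------

    def validate_dn_range(self):
        """Check the DN invariant: every valid cell is an integer in [0, 63].

        Applies to source rasters; resampled products may hold fractional
        values and are not expected to pass.
        """
        valid = self.values[~self.nodata_mask]
        if valid.size == 0:
            return
        if np.any((valid < DN_MIN) | (valid > DN_MAX)):
            raise ValueError("DN values outside [0, 63]")
        if not np.allclose(valid, np.round(valid)):
            raise ValueError("DN values must be integers before resampling")


# -- text raster I/O (ESRI ASCII grid convention) ---------------------------


def read_ascii_grid(path, crs="lonlat", nodata_default=DEFAULT_NODATA) -> LightRaster:
    """Read a single-band raster from an ESRI ASCII grid file.

    The nodata value is taken from the ``NODATA_value`` header when present,
    otherwise ``nodata_default`` (255, the convention for byte rasters).
    """
    header = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", float(nodata_default))
    values = np.loadtxt(data_lines).reshape(nrows, ncols)
    mask = values == nodata
    cs = header["cellsize"]
    # ASCII grids anchor at the lower-left corner; convert to top-left origin.
    gt = (header["xllcorner"], cs, 0.0, header["yllcorner"] + nrows * cs, 0.0, -cs)
    if np.allclose(values[~mask], np.round(values[~mask])):
        out = values.astype(np.int64)
        out[mask] = int(nodata)
        values = out
    return LightRaster(values, mask, gt, parse_crs(crs))


def write_ascii_grid(raster: LightRaster, path, nodata=DEFAULT_NODATA):
    """Write a raster as an ESRI ASCII grid (square cells required)."""
    x0, dx, _, y0, _, dy = raster.geotransform
    if not np.isclose(dx, -dy):
        raise ValueError("ASCII grid requires square cells")
    nrows, ncols = raster.shape
    vals = np.array(raster.values, dtype=float)
    vals[raster.nodata_mask] = nodata
    integral = np.allclose(vals, np.round(vals))
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {y0 + nrows * dy:.10g}\n")
        fh.write(f"cellsize {dx:.10g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if integral else "%.8g"
        np.savetxt(fh, vals, fmt=fmt)


# -- resampling -------------------------------------------------------------


def _keys_cubic_weights(t):
    """Keys cubic-convolution weights (a = -0.5) for taps at -1, 0, +1, +2.

    ``t`` is the fractional offset in [0, 1) from the tap at 0.
    """
    a = -0.5

    def k(d):
        d = np.abs(d)
        w = np.where(
            d <= 1.0,
            (a + 2.0) * d**3 - (a + 3.0) * d**2 + 1.0,
            np.where(d < 2.0, a * (d**3 - 5.0 * d**2 + 8.0 * d - 4.0), 0.0),
        )
        return w

    return np.stack([k(t + 1.0), k(t), k(1.0 - t), k(2.0 - t)], axis=0)


def _interpolate(values, mask, rows, cols, method):
    """Sample ``values`` at fractional (rows, cols); returns (out, invalid).

    A sample is invalid when its interpolation support leaves the grid or
    touches a nodata cell (nodata is propagated conservatively).
    """
    nrows, ncols = values.shape
    vals = values.astype(float)

    if method == "nearest":
        r = np.round(rows).astype(np.int64)
        c = np.round(cols).astype(np.int64)
        invalid = (r < 0) | (r >= nrows) | (c < 0) | (c >= ncols)
        rc = np.clip(r, 0, nrows - 1)
        cc = np.clip(c, 0, ncols - 1)
        out = values[rc, cc]
        invalid |= mask[rc, cc]
        return out, invalid

    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    tr = rows - r0
    tc = cols - c0

    if method == "bilinear":
        offsets = (0, 1)
        wr = np.stack([1.0 - tr, tr], axis=0)
        wc = np.stack([1.0 - tc, tc], axis=0)
    elif method == "cubic":
        offsets = (-1, 0, 1, 2)
        wr = _keys_cubic_weights(tr)
        wc = _keys_cubic_weights(tc)
    else:
        raise ValueError(f"unknown resampling method: {method!r}")

    out = np.zeros(rows.shape, dtype=float)
    invalid = np.zeros(rows.shape, dtype=bool)
    for i, dr in enumerate(offsets):
        rr = r0 + dr
        oob_r = (rr < 0) | (rr >= nrows)
        rrc = np.clip(rr, 0, nrows - 1)
        for j, dc in enumerate(offsets):
            cc = c0 + dc
            oob = oob_r | (cc < 0) | (cc >= ncols)
            ccc = np.clip(cc, 0, ncols - 1)
            invalid |= oob | mask[rrc, ccc]
            out += wr[i] * wc[j] * vals[rrc, ccc]
    return out, invalid


def reproject_resample(raster: LightRaster, target_crs, cell_size,
                       method="cubic") -> LightRaster:
    """Reproject a raster to ``target_crs`` on a grid of ``cell_size``.

    ``method`` is one of ``nearest``, ``bilinear``, ``cubic`` (cubic
    convolution, Keys a = -0.5, the sharpening resampler conventional for
    continuous imagery). Cubic output is clamped back into the DN range
    [0, 63] but kept fractional, so zonal sums remain interpolation-faithful.

    When the target CRS equals the source CRS the output grid is anchored at
    the source origin, making identity resampling at the native cell size
    bit-exact under ``nearest``.
    """
    if method not in ("nearest", "bilinear", "cubic"):
        raise ValueError(f"method must be nearest|bilinear|cubic, got {method!r}")
    if raster.values.size == 0:
        raise ValueError("cannot resample an empty raster")
    target = parse_crs(target_crs)
    cell_size = float(cell_size)
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")

    x0, dx, _, y0, _, dy = raster.geotransform
    nrows, ncols = raster.shape

    if target == raster.crs:
        out_x0, out_y0 = x0, y0
        width = ncols * abs(dx)
        height = nrows * abs(dy)
    else:
        # Project a densified boundary of the source extent to find the
        # target-frame bounding box.
        t = np.linspace(0.0, 1.0, 65)
        xs = x0 + t * ncols * dx
        ys = y0 + t * nrows * dy
        bx = np.concatenate([xs, xs, np.full_like(ys, xs[0]), np.full_like(ys, xs[-1])])
        by = np.concatenate([np.full_like(xs, ys[0]), np.full_like(xs, ys[-1]), ys, ys])
        lon, lat = raster.crs.inverse(bx, by)
        tx, ty = target.forward(lon, lat)
        out_x0, out_y0 = float(tx.min()), float(ty.max())
        width = float(tx.max() - tx.min())
        height = float(ty.max() - ty.min())

    out_ncols = max(1, int(np.ceil(width / cell_size - 1e-9)))
    out_nrows = max(1, int(np.ceil(height / cell_size - 1e-9)))
    out_gt = (out_x0, cell_size, 0.0, out_y0, 0.0, -cell_size)

    oc = np.arange(out_ncols) + 0.5
    orow = np.arange(out_nrows) + 0.5
    ox, oy = np.meshgrid(out_x0 + oc * cell_size, out_y0 - orow * cell_size)
    lon, lat = target.inverse(ox, oy)
    sx, sy = raster.crs.forward(lon, lat)
    rows, cols = raster.coords_to_fractional_index(sx, sy)

    out, invalid = _interpolate(raster.values, raster.nodata_mask, rows, cols, method)
    if method == "cubic":
        out = np.clip(out, DN_MIN, DN_MAX)
    if method == "nearest":
        out = np.asarray(out)
    out = np.where(invalid, 0, out)
    if invalid.all():
        logger.warning("resampled raster contains no valid cells")
    return LightRaster(out, invalid, out_gt, target)
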