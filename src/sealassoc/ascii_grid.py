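"""ESRI ASCII grid raster I/O and nearest-cell lookup.

The bathymetry used here is a plain ESRI ASCII grid (``ncols``/``nrows``/
``xllcorner``/``yllcorner``/``cellsize``/``NODATA_value`` header followed by
``nrows`` rows of values, northernmost row first).  Depths are positive
metres (positive down).  Values are written with ``repr`` so a write/read
round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["BathymetryRaster", "read_ascii_grid", "write_ascii_grid", "depth_at"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class BathymetryRaster:
    """Rectangular grid of depths (m, positive down).

    ``values[0, :]`` is the northernmost row, matching the file layout.
    """

    values: np.ndarray          # (nrows, ncols)
    xllcorner: float
    yllcorner: float
    cellsize: float             # decimal degrees
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max)."""
        return (self.xllcorner,
                self.xllcorner + self.ncols * self.cellsize,
                self.yllcorner,
                self.yllcorner + self.nrows * self.cellsize)


def read_ascii_grid(path) -> BathymetryRaster:
    """Parse an ESRI ASCII grid.  Malformed headers are a hard error."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {values.shape} does not match header")
    return BathymetryRaster(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: BathymetryRaster, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner!r}\n")
        fh.write(f"yllcorner {raster.yllcorner!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def depth_at(raster: BathymetryRaster, lon, lat):
    """Nearest-cell depth lookup.

    Returns NaN (with a logged warning) for positions outside the extent and
    for NODATA cells.  Accepts scalars or arrays.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    scalar = lon.ndim == 0
    lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)

    col = np.floor((lon - raster.xllcorner) / raster.cellsize).astype(int)
    row_from_bottom = np.floor((lat - raster.yllcorner) / raster.cellsize).astype(int)
    inside = ((col >= 0) & (col < raster.ncols)
              & (row_from_bottom >= 0) & (row_from_bottom < raster.nrows)
              & np.isfinite(lon) & np.isfinite(lat))
    out = np.full(lon.shape, np.nan)
    r = raster.nrows - 1 - row_from_bottom[inside]
    vals = raster.values[r, col[inside]]
    vals = np.where(vals == raster.nodata, np.nan, vals)
    out[inside] = vals
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("depth_at: %d position(s) outside raster extent -> missing", n_outside)
    return float(out[0]) if scalar else out
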