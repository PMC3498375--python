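"""Density-weighted availability sampling of habitat depths.

To characterise the depths *available* to each animal (rather than only
the depths it visited), a bivariate normal-kernel density surface is fit to
each track over a 500 x 220 lon/lat grid and used as the sampling intensity
for random locations; bottom depths at the sampled locations form the
"random" category of the depth comparison.  Sample sizes are allocated
across animals in direct proportion to their number of locations.

The density estimator matches the classical product-kernel estimator with
axis-wise normal-reference bandwidths (1.06 * min(sd, IQR/1.34) * n^(-1/5)
as the kernel standard deviation per axis), evaluated at cell centres and
computed in lon/lat degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ascii_grid import BathymetryRaster, depth_at

log = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "nrd_bandwidth",
    "kde2d",
    "allocate_sample_sizes",
    "sample_locations",
    "sample_depths",
]

GRID_SHAPE = (500, 220)  # (lon cells, lat cells)


@dataclass
class DensityGrid:
    """KDE surface on a regular lon/lat grid.

    ``density[i, j]`` is the density at cell centre ``(x_centres[i],
    y_centres[j])``; ``hx, hy`` are the kernel standard deviations used.
    """

    density: np.ndarray      # (nx, ny), non-negative
    x_centres: np.ndarray
    y_centres: np.ndarray
    hx: float
    hy: float
    cell_dx: float = 0.0     # derived from centres when left at 0
    cell_dy: float = 0.0

    def __post_init__(self) -> None:
        if not self.cell_dx:
            self.cell_dx = float(self.x_centres[1] - self.x_centres[0]) \
                if len(self.x_centres) > 1 else 1.0
        if not self.cell_dy:
            self.cell_dy = float(self.y_centres[1] - self.y_centres[0]) \
                if len(self.y_centres) > 1 else 1.0

    @property
    def mass(self) -> float:
        """Total probability mass inside the grid (approaches 1 when the
        point cloud sits well inside the padded extent)."""
        return float(self.density.sum() * self.cell_dx * self.cell_dy)


def nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference kernel standard deviation for one axis:
    1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q25, q75 = np.quantile(x, [0.25, 0.75])
    iqr = (q75 - q25) / 1.34
    spread = min(sd, iqr) if iqr > 0 else sd
    h = 1.06 * spread * len(x) ** (-0.2)
    if h <= 0:
        raise ValueError("zero bandwidth: points have no spread on an axis")
    return h


def kde2d(points: np.ndarray, grid_shape: tuple[int, int] = GRID_SHAPE,
          extent: tuple[float, float, float, float] | None = None) -> DensityGrid:
    """Bivariate product-normal kernel density surface for one track.

    ``points`` is (n, 2) lon/lat.  The grid covers the point bounding box
    padded by one kernel bandwidth per side (or the given ``extent`` =
    (lon_min, lon_max, lat_min, lat_max)), with densities evaluated at the
    ``grid_shape`` cell centres.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    x, y = pts[:, 0], pts[:, 1]
    hx, hy = nrd_bandwidth(x), nrd_bandwidth(y)
    nx, ny = grid_shape
    if extent is None:
        extent = (x.min() - hx, x.max() + hx, y.min() - hy, y.max() + hy)
    x0, x1, y0, y1 = extent
    dx, dy = (x1 - x0) / nx, (y1 - y0) / ny
    xc = x0 + (np.arange(nx) + 0.5) * dx
    yc = y0 + (np.arange(ny) + 0.5) * dy
    # separable kernel: density = (Kx @ Ky^T) / n
    kx = stats.norm.pdf((xc[:, None] - x[None, :]) / hx) / hx   # (nx, n)
    ky = stats.norm.pdf((yc[:, None] - y[None, :]) / hy) / hy   # (ny, n)
    density = (kx @ ky.T) / len(x)
    return DensityGrid(density=density, x_centres=xc, y_centres=yc,
                       hx=hx, hy=hy, cell_dx=dx, cell_dy=dy)


def allocate_sample_sizes(track_lengths, total: int) -> np.ndarray:
    """Apportion ``total`` random locations across animals in direct
    proportion to their track lengths (largest-remainder rounding, ties
    broken by position).  The counts always sum to ``total``."""
    lengths = np.asarray(track_lengths, dtype=float)
    if len(lengths) == 0 or lengths.sum() <= 0:
        raise ValueError("total track length must be positive")
    if total < len(lengths):
        raise ValueError("total must be >= number of animals")
    quota = total * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    shortfall = int(total - base.sum())
    if shortfall:
        order = np.lexsort((np.arange(len(lengths)), -(quota - base)))
        base[order[:shortfall]] += 1
    return base


def sample_locations(grid: DensityGrid, n: int, seed) -> np.ndarray:
    """Draw ``n`` random lon/lat locations with cell probability
    proportional to density mass, jittered uniformly within the cell.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Deterministic
    given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = grid.density.ravel()
    total = w.sum()
    if not total > 0:
        raise ValueError("all-zero density grid")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.choice(len(w), size=n, p=w / total)
    ix, iy = np.unravel_index(idx, grid.density.shape)
    lon = grid.x_centres[ix] + rng.uniform(-0.5, 0.5, n) * grid.cell_dx
    lat = grid.y_centres[iy] + rng.uniform(-0.5, 0.5, n) * grid.cell_dy
    return np.column_stack([lon, lat])


def sample_depths(locations: np.ndarray, raster: BathymetryRaster) -> np.ndarray:
    """Nearest-cell depths at sampled locations.

    Returns one value per location; NaN (counted and logged) where the
    location falls outside the raster or on NODATA.  Downstream summaries
    exclude the NaNs.
    """
    locations = np.asarray(locations, dtype=float)
    if len(locations) == 0:
        return np.empty(0)
    depths = depth_at(raster, locations[:, 0], locations[:, 1])
    n_missing = int(np.isnan(depths).sum())
    if n_missing:
        log.info("sample_depths: %d of %d locations have no depth",
                 n_missing, len(depths))
    return depths
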