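"""Archival GPS track cleaning and 60-min discretisation.

Fastloc-style fixes are graded by satellite count and residual error;
fixes from fewer than 5 satellites or with residual error above 30 are
removed.  Tracks are then divided into 60-min time-steps aligned to UTC
hours (24 steps per day), positions averaged within each step, and travel
rate computed as the distance between consecutive step positions over the
elapsed time.  Bathymetric depth is attached by nearest-cell lookup, and
each step is flagged if any located association of that animal overlaps
the step window.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ascii_grid import BathymetryRaster, read_ascii_grid, depth_at
from .geo import haversine_m
from .timebase import from_iso

log = logging.getLogger(__name__)

__all__ = [
    "read_gps_log",
    "filter_fixes",
    "bin_steps",
    "travel_rates",
    "attach_depths",
    "flag_association_steps",
    "read_bathymetry",
    "depth_at",
]

STEP_S = 3600.0

read_bathymetry = read_ascii_grid


def read_gps_log(path) -> pd.DataFrame:
    """Parse a GPS log (``seal_id,timestamp,lon,lat,n_sats,residual``).

    Malformed lines are skipped with a logged count
    (``df.attrs['n_skipped']``); a wrong header is a hard error.
    """
    path = Path(path)
    with path.open() as fh:
        header = [h.strip() for h in fh.readline().strip().split(",")]
        required = ["seal_id", "timestamp", "lon", "lat", "n_sats", "residual"]
        if header != required:
            raise ValueError(f"{path}: expected header {','.join(required)!r}")
        rows, n_skipped = [], 0
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 6:
                n_skipped += 1
                continue
            try:
                rows.append((parts[0], from_iso(parts[1]), float(parts[2]),
                             float(parts[3]), int(parts[4]), float(parts[5])))
            except (ValueError, OverflowError):
                n_skipped += 1
    df = pd.DataFrame(rows, columns=["seal_id", "t", "lon", "lat",
                                     "n_sats", "residual"])
    df = df.sort_values(["seal_id", "t"]).reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    if n_skipped:
        log.info("%s: skipped %d malformed line(s)", path, n_skipped)
    return df


def filter_fixes(fixes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop low-accuracy fixes: fewer than 5 satellites and/or residual
    error above 30.  Boundary values (exactly 5 satellites, residual
    exactly 30) are kept.  Returns ``(kept, removed_count)``."""
    keep = (fixes["n_sats"] >= 5) & (fixes["residual"] <= 30.0)
    kept = fixes[keep].reset_index(drop=True)
    return kept, int(len(fixes) - len(kept))


def bin_steps(fixes: pd.DataFrame, step_s: float = STEP_S) -> pd.DataFrame:
    """Average fixes into hour-aligned time-steps.

    Windows are half-open ``[k*step_s, (k+1)*step_s)`` aligned to UTC hours.
    The mean position is the arithmetic mean of lon and of lat over the
    window's fixes; windows with no fixes are absent from the output.

    Returns ``seal_id, step, t_mid, lon, lat, n_fixes`` sorted per seal.
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=["seal_id", "step", "t_mid", "lon",
                                     "lat", "n_fixes"])
    f = fixes.copy()
    f["step"] = np.floor(f["t"].to_numpy() / step_s).astype(int)
    out = (f.groupby(["seal_id", "step"], sort=True)
            .agg(lon=("lon", "mean"), lat=("lat", "mean"), n_fixes=("t", "size"))
            .reset_index())
    out["t_mid"] = (out["step"] + 0.5) * step_s
    return out[["seal_id", "step", "t_mid", "lon", "lat", "n_fixes"]]


def travel_rates(steps: pd.DataFrame) -> pd.DataFrame:
    """Add ``rate_ms`` (m s^-1): distance between the mean positions of
    adjacent steps divided by the elapsed time between window centres.

    A step's rate is missing unless the immediately preceding window (step
    index - 1) is present for the same seal.  The hourly displacement used
    by the movement-state model is ``rate_ms * 3600``.
    """
    out = steps.sort_values(["seal_id", "step"]).reset_index(drop=True).copy()
    rate = np.full(len(out), np.nan)
    for _, grp in out.groupby("seal_id", sort=False):
        idx = grp.index.to_numpy()
        stepno = grp["step"].to_numpy()
        lon, lat = grp["lon"].to_numpy(), grp["lat"].to_numpy()
        tmid = grp["t_mid"].to_numpy()
        if len(idx) < 2:
            continue
        adjacent = np.diff(stepno) == 1
        d = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        dt = np.diff(tmid)
        r = np.where(adjacent, d / dt, np.nan)
        rate[idx[1:]] = r
    out["rate_ms"] = rate
    return out


def attach_depths(steps: pd.DataFrame, raster: BathymetryRaster) -> pd.DataFrame:
    """Add ``depth_m`` by nearest-cell bathymetry lookup at the step's mean
    position (NaN outside the raster or at NODATA cells)."""
    out = steps.copy()
    out["depth_m"] = depth_at(raster, out["lon"].to_numpy(), out["lat"].to_numpy())
    return out


def flag_association_steps(steps: pd.DataFrame,
                           associations: pd.DataFrame,
                           step_s: float = STEP_S) -> pd.DataFrame:
    """Add a boolean ``associated`` column.

    A step is flagged iff any association involving that seal intersects
    the half-open step window ``[t, t+step_s)``; a single association can
    span (and flag) several consecutive steps.
    """
    out = steps.copy()
    flag = np.zeros(len(out), dtype=bool)
    if len(associations):
        win_start = out["step"].to_numpy() * step_s
        win_end = win_start + step_s
        sid = out["seal_id"].to_numpy()
        for row in associations.itertuples(index=False):
            involved = (sid == row.seal_a) | (sid == row.seal_b)
            overlap = (row.start < win_end) & (row.end >= win_start)
            flag |= involved & overlap
    out["associated"] = flag
    return out
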