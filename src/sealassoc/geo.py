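"""Spherical geodesy helpers shared across the package.

All positions are WGS84 lon/lat decimal degrees; distances are computed on a
sphere of radius 6371.0088 km (IUGG mean Earth radius) with the haversine
formula, which is ample for the sub-200-km scales of shelf-foraging tracks.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

__all__ = ["EARTH_RADIUS_M", "haversine_m", "step_lonlat", "bearing_rad"]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(np.radians(v), dtype=float)
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def step_lonlat(lon, lat, distance_m, heading_rad):
    """Displace a point by ``distance_m`` along ``heading_rad`` (0 = north,
    pi/2 = east), using a local flat-earth approximation.

    Adequate for the <10 km hourly steps simulated here; error is O((d/R)^2).
    """
    dn = distance_m * np.cos(heading_rad)
    de = distance_m * np.sin(heading_rad)
    dlat = np.degrees(dn / EARTH_RADIUS_M)
    dlon = np.degrees(de / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return lon + dlon, lat + dlat


def bearing_rad(lon1, lat1, lon2, lat2):
    """Initial bearing from point 1 to point 2 (radians, 0 = north), on the
    local equirectangular plane."""
    de = np.radians(np.asarray(lon2) - np.asarray(lon1)) * np.cos(np.radians(lat1))
    dn = np.radians(np.asarray(lat2) - np.asarray(lat1))
    return np.arctan2(de, dn)
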