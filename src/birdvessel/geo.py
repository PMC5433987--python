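"""Great-circle geometry on the sphere (no projections).

At the scales that matter here (attendance within 3 km, attraction within
30 km) spherical distances with R = 6371 km are accurate to well below the
GPS noise floor, so everything stays projection-free.
"""

from __future__ import annotations

import numpy as np

from .params import AnalysisParams
from .types import validate_coords

EARTH_RADIUS_KM = 6371.0


def _hav_scalar(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Unchecked scalar haversine for tight simulation loops."""
    from math import asin, cos, radians, sin, sqrt
    p1, p2 = radians(lat1), radians(lat2)
    a = (sin(radians(lat2 - lat1) / 2.0) ** 2
         + cos(p1) * cos(p2) * sin(radians(lon2 - lon1) / 2.0) ** 2)
    return 2.0 * radius_km * asin(min(1.0, sqrt(a)))


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points in degrees.

    Accepts scalars or broadcastable arrays; symmetric and nonnegative.
    """
    validate_coords(lon1, lat1)
    validate_coords(lon2, lat2)
    if (isinstance(lon1, float) and isinstance(lat1, float)
            and isinstance(lon2, float) and isinstance(lat2, float)):
        return _hav_scalar(lon1, lat1, lon2, lat2, radius_km)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.isscalar(lon1) or d.ndim == 0:
        return float(d)
    return d


def ground_speed_kmh(t_prev, lon_prev, lat_prev, t_curr, lon_curr, lat_curr,
                     radius_km: float = EARTH_RADIUS_KM) -> float:
    """Speed over one track segment: haversine distance / elapsed hours."""
    dt_h = (np.datetime64(t_curr) - np.datetime64(t_prev)) / np.timedelta64(1, "h")
    if dt_h <= 0:
        raise ValueError("ground speed needs strictly increasing timestamps")
    return haversine_km(lon_prev, lat_prev, lon_curr, lat_curr, radius_km) / dt_h


def track_speeds_kmh(timestamps, lon, lat, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Per-fix backward-difference speeds for a whole track.

    The speed at fix i is computed over the segment from fix i-1 to fix i;
    the first fix copies the following segment's speed, so attendance
    classification uses only past movement except at the very start of a
    trip.  A single-fix track gets speed 0.
    """
    ts = np.asarray(timestamps, dtype="datetime64[ns]")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(ts)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.zeros(1)
    dt_h = np.diff(ts) / np.timedelta64(1, "h")
    if np.any(dt_h <= 0):
        raise ValueError("timestamps must be strictly increasing")
    seg = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:], radius_km) / dt_h
    speeds = np.empty(n)
    speeds[1:] = seg
    speeds[0] = seg[0]
    return speeds


def destination_point(lon, lat, bearing_deg, distance_km,
                      radius_km: float = EARTH_RADIUS_KM):
    """Point reached from (lon, lat) moving ``distance_km`` on ``bearing_deg``.

    Standard great-circle forward solution; used by the trajectory
    simulators.  Returns (lon, lat) in degrees with lon wrapped to
    [-180, 180).
    """
    lam1, phi1 = np.radians(lon), np.radians(lat)
    theta = np.radians(bearing_deg)
    delta = np.asarray(distance_km, dtype=float) / radius_km
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    lat2 = np.degrees(phi2)
    if np.isscalar(lon) and np.ndim(lon2) == 0:
        return float(lon2), float(lat2)
    return lon2, lat2


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2 (degrees)."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    y = np.sin(lam2 - lam1) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(lam2 - lam1)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    return float(b) if np.ndim(b) == 0 else b


def speeds_for_params(timestamps, lon, lat, params: AnalysisParams) -> np.ndarray:
    return track_speeds_kmh(timestamps, lon, lat, params.earth_radius_km)
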