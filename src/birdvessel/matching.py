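"""Spatiotemporal join of bird fixes to vessel trajectories.

For each bird fix and each vessel, the vessel grid point minimizing the
absolute time difference is selected subject to |dt| <= match_tol (ties
broken toward the earlier vessel point), and the great-circle distance is
computed.  With vessels on a 10-min grid and a 5-min tolerance, every
bird fix inside a vessel's span matches exactly one point of that vessel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import haversine_km, track_speeds_kmh
from .params import AnalysisParams
from .solar import solar_elevation
from .types import BirdTrack, VesselTrack


def _match_times(bird_ts: np.ndarray, vessel_ts: np.ndarray,
                 tol: np.timedelta64) -> np.ndarray:
    """Index into vessel_ts of the best time match per bird fix, or -1.

    Ties at exactly the tolerance on both sides go to the earlier vessel
    point, for determinism.
    """
    idx = np.searchsorted(vessel_ts, bird_ts)
    n = len(vessel_ts)
    left = np.clip(idx - 1, 0, n - 1)
    right = np.clip(idx, 0, n - 1)
    dt_left = np.abs(bird_ts - vessel_ts[left])
    dt_right = np.abs(bird_ts - vessel_ts[right])
    # <= prefers the earlier (left) point on ties
    best = np.where(dt_left <= dt_right, left, right)
    best_dt = np.minimum(dt_left, dt_right)
    return np.where(best_dt <= tol, best, -1)


def match_locations(bird: BirdTrack, vessels: list[VesselTrack],
                    params: AnalysisParams | None = None) -> pd.DataFrame:
    """Annotate every fix of one bird trip against all vessel tracks.

    Returns one row per bird fix with the columns documented in
    :data:`birdvessel.types.MATCHED_COLUMNS`.  A fix outside every
    vessel's span simply matches zero vessels.
    """
    params = params or AnalysisParams()
    fixes = bird.fixes
    n = len(fixes)
    bird_ts = fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
    blon = fixes["lon"].to_numpy()
    blat = fixes["lat"].to_numpy()
    tol = np.timedelta64(int(round(params.match_tol_min * 60)), "s")

    speeds = track_speeds_kmh(bird_ts, blon, blat, params.earth_radius_km)
    daylight = (np.asarray(solar_elevation(bird_ts, blon, blat))
                > params.daylight_elev_deg)

    dist_by_vessel: dict[str, np.ndarray] = {}
    act_by_vessel: dict[str, np.ndarray] = {}
    for vt in sorted(vessels, key=lambda v: v.vessel_id):
        vts = vt.points["timestamp"].to_numpy(dtype="datetime64[ns]")
        if len(vts) == 0:
            continue
        midx = _match_times(bird_ts, vts, tol)
        ok = midx >= 0
        d = np.full(n, np.nan)
        if ok.any():
            vlon = vt.points["lon"].to_numpy()[midx[ok]]
            vlat = vt.points["lat"].to_numpy()[midx[ok]]
            d[ok] = haversine_km(blon[ok], blat[ok], vlon, vlat,
                                 params.earth_radius_km)
        act = np.array([None] * n, dtype=object)
        act[ok] = vt.points["activity"].to_numpy(dtype=object)[midx[ok]]
        dist_by_vessel[vt.vessel_id] = d
        act_by_vessel[vt.vessel_id] = act

    vids = sorted(dist_by_vessel)
    if vids:
        dmat = np.vstack([dist_by_vessel[v] for v in vids])  # (n_vessels, n)
        with np.errstate(invalid="ignore"):
            n_in_attr = np.nansum(dmat < params.attraction_km, axis=0).astype(int)
        all_nan = np.all(np.isnan(dmat), axis=0)
        # lexicographically-smallest vessel wins distance ties: nanargmin
        # scans rows in sorted-vid order and keeps the first minimum
        safe = np.where(np.isnan(dmat), np.inf, dmat)
        argmin = np.argmin(safe, axis=0)
        nearest_d = np.where(all_nan, np.nan, safe[argmin, np.arange(n)])
        nearest_v = np.where(all_nan, None,
                             np.array(vids, dtype=object)[argmin])
        nearest_a = np.array([
            None if all_nan[i] else act_by_vessel[vids[argmin[i]]][i]
            for i in range(n)], dtype=object)
    else:
        n_in_attr = np.zeros(n, dtype=int)
        nearest_d = np.full(n, np.nan)
        nearest_v = np.array([None] * n, dtype=object)
        nearest_a = np.array([None] * n, dtype=object)

    with np.errstate(invalid="ignore"):
        in_attraction = np.where(np.isnan(nearest_d), False,
                                 nearest_d < params.attraction_km).astype(bool)
        is_attendance = (in_attraction
                         & np.where(np.isnan(nearest_d), False,
                                    nearest_d < params.attendance_km)
                         & (speeds < params.sit_speed_kmh))

    vessel_dicts = [
        {v: float(dist_by_vessel[v][i]) for v in vids
         if not np.isnan(dist_by_vessel[v][i])}
        for i in range(n)
    ]
    return pd.DataFrame({
        "bird_id": bird.bird_id, "trip_id": bird.trip_id,
        "timestamp": bird_ts, "lon": blon, "lat": blat,
        "speed_kmh": speeds, "is_daylight": daylight,
        "vessel_distances": vessel_dicts, "n_in_attraction": n_in_attr,
        "nearest_vessel_id": nearest_v,
        "nearest_distance_km": nearest_d, "nearest_activity": nearest_a,
        "in_attraction": in_attraction, "is_attendance": is_attendance,
    })


def match_all(birds: list[BirdTrack], vessels: list[VesselTrack],
              params: AnalysisParams | None = None) -> pd.DataFrame:
    """Concatenated matched frame over many trips."""
    frames = [match_locations(b, vessels, params) for b in birds]
    if not frames:
        return pd.DataFrame(columns=["bird_id", "trip_id"])
    return pd.concat(frames, ignore_index=True)
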