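"""Sensitivity of the headline attendance statistics to the two
segmentation thresholds: attraction range and time-to-return.

The matched locations are computed once; each grid cell re-derives
in-range flags at its attraction radius, re-segments, re-applies the
daylight-flying filter, and recomputes the headline statistics.
Attendance classification itself (the 3-km sitting rule) is fixed; a
cell only changes which fixes pass the attraction gate and how events
merge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .encounters import filter_daylight_flying, segment_encounters
from .params import AnalysisParams

DEFAULT_ATTRACTION_GRID_KM = (15.0, 20.0, 25.0, 30.0)
DEFAULT_TIME_TO_RETURN_GRID_HR = (0.5, 1.0, 2.0, 6.0, 12.0, 24.0)


def hours_to_locs(hours: float, bird_dt_min: float) -> int:
    """Convert a time-to-return expressed in hours to a fix count."""
    locs = int(round(hours * 60.0 / bird_dt_min))
    if locs < 1:
        raise ValueError(
            f"time-to-return of {hours} hr is below one fix interval")
    return locs


def _cell_params(params: AnalysisParams, attraction_km: float,
                 ttr_locs: int) -> AnalysisParams:
    return dataclasses.replace(params, attraction_km=attraction_km,
                               time_to_return_locs=ttr_locs)


def reclassify(matched: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Re-derive in_attraction / is_attendance at a new attraction radius.

    Uses the stored per-vessel distances, so the expensive spatiotemporal
    join is not repeated.
    """
    out = matched.copy()
    dmin = out["nearest_distance_km"].to_numpy()
    with np.errstate(invalid="ignore"):
        in_attr = np.where(np.isnan(dmin), False, dmin < params.attraction_km)
        n_in = np.array([sum(1 for v in d.values() if v < params.attraction_km)
                         for d in out["vessel_distances"]])
        att = (in_attr
               & np.where(np.isnan(dmin), False, dmin < params.attendance_km)
               & (out["speed_kmh"].to_numpy() < params.sit_speed_kmh))
    out["in_attraction"] = in_attr.astype(bool)
    out["is_attendance"] = att.astype(bool)
    out["n_in_attraction"] = n_in
    return out


def cell_statistics(matched_all: pd.DataFrame,
                    params: AnalysisParams) -> dict:
    """Headline statistics of one grid cell (given cell-specific params)."""
    n_events = 0
    n_with_att = 0
    att_durs = []
    att_props = []
    trips_total = 0
    trips_with_event = 0
    for _, grp in matched_all.groupby("trip_id", sort=True):
        trips_total += 1
        evs = filter_daylight_flying(segment_encounters(grp, params), params)
        evs = [e for e in evs if e.retained_daylight]
        if evs:
            trips_with_event += 1
        for e in evs:
            n_events += 1
            if e.has_attendance:
                n_with_att += 1
                att_durs.append(e.n_attendance * params.bird_dt_min / 60.0)
                att_props.append(e.n_attendance / e.n_locations)
    return {
        "n_encounters": n_events,
        "prop_trips_with_encounter": (trips_with_event / trips_total
                                      if trips_total else np.nan),
        "attendance_prob": n_with_att / n_events if n_events else np.nan,
        "mean_attendance_hr": float(np.mean(att_durs)) if att_durs else np.nan,
        "mean_attendance_prop": float(np.mean(att_props)) if att_props else np.nan,
    }


def sweep(matched_all: pd.DataFrame,
          attraction_grid_km=DEFAULT_ATTRACTION_GRID_KM,
          time_to_return_grid_hr=DEFAULT_TIME_TO_RETURN_GRID_HR,
          params: AnalysisParams | None = None) -> pd.DataFrame:
    """One row per (attraction radius, time-to-return) grid cell."""
    params = params or AnalysisParams()
    rows = []
    for r_km in attraction_grid_km:
        if r_km <= params.attendance_km:
            raise ValueError("attraction radius must exceed attendance range")
        for ttr_hr in time_to_return_grid_hr:
            ttr = hours_to_locs(ttr_hr, params.bird_dt_min)
            cell = _cell_params(params, r_km, ttr)
            m = reclassify(matched_all, cell)
            stats = cell_statistics(m, cell)
            rows.append({"attraction_km": r_km, "time_to_return_hr": ttr_hr,
                         "time_to_return_locs": ttr, **stats})
    return pd.DataFrame(rows)
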