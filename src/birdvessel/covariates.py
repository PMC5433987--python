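"""Event-level covariates, attendance metrics, and trip summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geo import haversine_km
from .params import AnalysisParams
from .types import BirdTrack, EncounterEvent, FishingOperation, VesselTrack


def time_to_fishing_hr(event_start, ops: list[FishingOperation],
                       vessel_ids) -> float:
    """Hours from encounter start to the closest fishing activity.

    0 if any of the event's vessels is in an operation at the encounter
    start; otherwise the minimum, across those vessels, of the time since
    the last operation ended and the time until the next one starts.
    NaN when the event's vessels have no operations on record.
    """
    t = np.datetime64(pd.Timestamp(event_start))
    vids = set(vessel_ids)
    best = np.inf
    any_op = False
    for op in ops:
        if op.vessel_id not in vids:
            continue
        any_op = True
        t0, t1 = np.datetime64(op.t_start), np.datetime64(op.t_end)
        if t0 <= t <= t1:
            return 0.0
        gap = (t - t1) if t > t1 else (t0 - t)
        best = min(best, gap / np.timedelta64(1, "h"))
    if not any_op:
        return float("nan")
    return float(best)


def prop_fishing(event: EncounterEvent) -> float:
    """Fraction of the event's fixes whose nearest vessel is in operation."""
    acts = event.locations["nearest_activity"].to_numpy(dtype=object)
    return float(np.mean([a in ("setting", "hauling") for a in acts]))


def attendance_metrics(event: EncounterEvent,
                       params: AnalysisParams | None = None) -> dict:
    """Duration, event share, and mean boat distance of attendance fixes.

    Only meaningful for events that contain attendance behavior.
    """
    params = params or AnalysisParams()
    if not event.has_attendance:
        raise ValueError("attendance_metrics requires an event with attendance")
    att = event.locations[event.locations["is_attendance"]]
    n_att = len(att)
    return {
        "duration_locs": n_att,
        "duration_hr": n_att * params.bird_dt_min / 60.0,
        "prop_of_event": n_att / event.n_locations,
        "mean_distance_m": float(att["nearest_distance_km"].mean() * 1000.0),
    }


def event_covariates(event: EncounterEvent, ops: list[FishingOperation],
                     year_group: str,
                     params: AnalysisParams | None = None) -> dict:
    """Attach the model covariates to one event (also stored on the event)."""
    params = params or AnalysisParams()
    cov = {
        "time_to_fishing_hr": time_to_fishing_hr(event.t_start, ops,
                                                 event.vessel_ids),
        "prop_fishing": prop_fishing(event),
        "avg_boats_in_range": float(event.locations["n_in_attraction"].mean()),
        "year_group": year_group,
    }
    if event.has_attendance:
        cov.update(attendance_metrics(event, params))
    event.covariates.update(cov)
    return cov


def events_frame(events: list[EncounterEvent],
                 birds_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per event, covariates as columns, for models and export.

    ``birds_meta`` (bird_id, sex, age, year, ...) is joined on bird_id when
    given.
    """
    rows = []
    for ev in events:
        row = {
            "trip_id": ev.trip_id,
            "bird_id": ev.locations["bird_id"].iloc[0],
            "event_index": ev.event_index,
            "t_start": ev.t_start, "t_end": ev.t_end,
            "n_locations": ev.n_locations, "n_attendance": ev.n_attendance,
            "has_attendance": ev.has_attendance,
            "retained_daylight": ev.retained_daylight,
            "vessel_ids": ";".join(ev.vessel_ids),
        }
        row.update(ev.covariates)
        rows.append(row)
    df = pd.DataFrame(rows)
    if birds_meta is not None and len(df):
        df = df.merge(birds_meta[["bird_id", "sex", "age", "year"]],
                      on="bird_id", how="left")
    return df


def _shelf_polygon(params: AnalysisParams) -> Polygon:
    return Polygon(params.shelf_polygon)


def in_region(lon, lat, polygon: Polygon) -> np.ndarray:
    """Point-in-polygon with on-boundary counted as inside."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    return np.array([polygon.covers(Point(x, y)) for x, y in zip(lon, lat)])


def boats_on_shelf_at(ts: np.ndarray, vessels: list[VesselTrack],
                      params: AnalysisParams) -> np.ndarray:
    """Count of vessels with an on-shelf track point at each instant.

    A vessel counts at instant t when it has a grid point within the match
    tolerance of t whose position lies inside the shelf polygon.
    """
    poly = _shelf_polygon(params)
    ts = np.asarray(ts, dtype="datetime64[ns]")
    tol = np.timedelta64(int(round(params.match_tol_min * 60)), "s")
    counts = np.zeros(len(ts), dtype=int)
    from .matching import _match_times
    for vt in vessels:
        vts = vt.points["timestamp"].to_numpy(dtype="datetime64[ns]")
        if len(vts) == 0:
            continue
        midx = _match_times(ts, vts, tol)
        ok = midx >= 0
        if not ok.any():
            continue
        lon = vt.points["lon"].to_numpy()[midx[ok]]
        lat = vt.points["lat"].to_numpy()[midx[ok]]
        inside = in_region(lon, lat, poly)
        counts[np.flatnonzero(ok)[inside]] += 1
    return counts


def trip_summary(bird: BirdTrack, events: list[EncounterEvent],
                 vessels: list[VesselTrack],
                 params: AnalysisParams | None = None) -> dict:
    """Trip-level statistics over this trip's (retained) events.

    ``avg_boats_present`` averages, over the trip's bird-fix instants, the
    number of vessels having an active on-shelf track point at that
    instant; ``n_encounters`` counts retained events only.
    """
    params = params or AnalysisParams()
    fixes = bird.fixes
    ts = fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
    lon, lat = fixes["lon"].to_numpy(), fixes["lat"].to_numpy()
    duration_days = float((ts[-1] - ts[0]) / np.timedelta64(1, "D"))
    clon, clat = params.colony
    max_range = float(np.max(haversine_km(lon, lat, clon, clat,
                                          params.earth_radius_km)))
    total_dist = float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:],
                                           params.earth_radius_km))) if len(ts) > 1 else 0.0
    poly = _shelf_polygon(params)
    prop_shelf = float(np.mean(in_region(lon, lat, poly)))
    avg_boats = float(np.mean(boats_on_shelf_at(ts, vessels, params)))

    evs = [e for e in events if e.trip_id == bird.trip_id
           and (e.retained_daylight is None or e.retained_daylight)]
    n_att_locs = sum(e.n_attendance for e in evs)
    att_hr = n_att_locs * params.bird_dt_min / 60.0
    return {
        "trip_id": bird.trip_id, "bird_id": bird.bird_id,
        "sex": bird.sex, "age": bird.age, "year": bird.year,
        "duration_days": duration_days, "max_range_km": max_range,
        "total_distance_km": total_dist, "prop_on_shelf": prop_shelf,
        "avg_boats_present": avg_boats, "n_encounters": len(evs),
        "any_attendance": any(e.has_attendance for e in evs),
        "attendance_time_hr": att_hr,
        "attendance_prop_of_trip": (att_hr / (duration_days * 24.0)
                                    if duration_days > 0 else 0.0),
    }


def trip_summaries(birds: list[BirdTrack], events: list[EncounterEvent],
                   vessels: list[VesselTrack],
                   params: AnalysisParams | None = None) -> pd.DataFrame:
    return pd.DataFrame([trip_summary(b, events, vessels, params) for b in birds])
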