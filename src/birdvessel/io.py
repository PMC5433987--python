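"""CSV / GeoJSON readers and writers for the pipeline's table dialects.

Dialects (all timestamps ISO-8601 UTC):

* bird fixes:       bird_id,trip_id,timestamp,lat,lon
* bird metadata:    bird_id,sex,age,year,mass_departure,mass_return
                    (optional: days_nest_before,days_nest_after)
* VMS:              vessel_id,timestamp,lat,lon
* operations:       vessel_id,op_type,t_start,t_end,lat_start,lon_start,
                    lat_end,lon_end
* region polygon:   GeoJSON Polygon, coordinates in (lon, lat) order
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import BirdTrack, FishingOperation, Fix, VesselTrack, check_ops_disjoint


def _ts(col: pd.Series) -> pd.Series:
    out = pd.to_datetime(col, utc=True).dt.tz_localize(None)
    return out


def read_bird_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "trip_id": str})
    df["timestamp"] = _ts(df["timestamp"])
    return df.sort_values(["bird_id", "trip_id", "timestamp"]).reset_index(drop=True)


def read_bird_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "year": str})
    return df


def load_bird_tracks(fixes_path, metadata_path) -> list[BirdTrack]:
    fixes = read_bird_fixes(fixes_path)
    meta = read_bird_metadata(metadata_path).set_index("bird_id")
    tracks = []
    for (bird_id, trip_id), grp in fixes.groupby(["bird_id", "trip_id"], sort=True):
        m = meta.loc[bird_id]
        tracks.append(BirdTrack(
            bird_id=bird_id, trip_id=trip_id, sex=str(m["sex"]),
            age=int(m["age"]), year=str(m["year"]),
            fixes=grp[["timestamp", "lon", "lat"]].reset_index(drop=True),
            mass_departure=_opt_float(m.get("mass_departure")),
            mass_return=_opt_float(m.get("mass_return")),
        ))
    return tracks


def _opt_float(v):
    if v is None or pd.isna(v):
        return None
    return float(v)


def write_bird_fixes(tracks: list[BirdTrack], path) -> None:
    rows = []
    for tr in tracks:
        df = tr.fixes.copy()
        df.insert(0, "trip_id", tr.trip_id)
        df.insert(0, "bird_id", tr.bird_id)
        rows.append(df[["bird_id", "trip_id", "timestamp", "lat", "lon"]])
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_bird_metadata(tracks: list[BirdTrack], path) -> None:
    seen = {}
    for tr in tracks:
        seen[tr.bird_id] = dict(
            bird_id=tr.bird_id, sex=tr.sex, age=tr.age, year=tr.year,
            mass_departure=tr.mass_departure, mass_return=tr.mass_return,
        )
    pd.DataFrame(list(seen.values())).to_csv(path, index=False)


def read_vms(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"vessel_id": str})
    df["timestamp"] = _ts(df["timestamp"])
    return df.sort_values(["vessel_id", "timestamp"]).reset_index(drop=True)


def write_vms(df: pd.DataFrame, path) -> None:
    df[["vessel_id", "timestamp", "lat", "lon"]].to_csv(path, index=False)


def read_operations(path) -> list[FishingOperation]:
    df = pd.read_csv(path, dtype={"vessel_id": str})
    ops = []
    for r in df.itertuples():
        t0, t1 = pd.Timestamp(r.t_start), pd.Timestamp(r.t_end)
        ops.append(FishingOperation(
            vessel_id=r.vessel_id, op_type=r.op_type, t_start=t0, t_end=t1,
            pos_start=Fix(t0, float(r.lon_start), float(r.lat_start)),
            pos_end=Fix(t1, float(r.lon_end), float(r.lat_end)),
        ))
    check_ops_disjoint(ops)
    return ops


def write_operations(ops: list[FishingOperation], path) -> None:
    pd.DataFrame([dict(
        vessel_id=o.vessel_id, op_type=o.op_type,
        t_start=o.t_start, t_end=o.t_end,
        lat_start=o.pos_start.lat, lon_start=o.pos_start.lon,
        lat_end=o.pos_end.lat, lon_end=o.pos_end.lon,
    ) for o in ops]).to_csv(path, index=False)


def read_region_polygon(path) -> list[tuple]:
    """Read a GeoJSON Polygon (outer ring only) as a list of (lon, lat)."""
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "Feature":
        gj = gj["geometry"]
    if gj.get("type") != "Polygon":
        raise ValueError(f"expected a GeoJSON Polygon, got {gj.get('type')!r}")
    ring = gj["coordinates"][0]
    return [tuple(p) for p in ring]


def write_region_polygon(ring: list, path) -> None:
    ring = [list(p) for p in ring]
    if ring[0] != ring[-1]:
        ring = ring + [ring[0]]
    Path(path).write_text(json.dumps(
        {"type": "Polygon", "coordinates": [ring]}, indent=1))


def write_vessel_tracks(tracks: list[VesselTrack], path) -> None:
    rows = []
    for tr in tracks:
        df = tr.points.copy()
        df.insert(0, "vessel_id", tr.vessel_id)
        rows.append(df[["vessel_id", "timestamp", "lat", "lon",
                        "activity", "interpolated"]])
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_vessel_tracks(path) -> list[VesselTrack]:
    df = pd.read_csv(path, dtype={"vessel_id": str})
    df["timestamp"] = _ts(df["timestamp"])
    return [VesselTrack(vessel_id=vid,
                        points=grp[["timestamp", "lon", "lat",
                                    "activity", "interpolated"]].reset_index(drop=True))
            for vid, grp in df.groupby("vessel_id", sort=True)]
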