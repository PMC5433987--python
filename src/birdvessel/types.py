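"""Domain containers shared across the pipeline.

Tracks are carried as pandas DataFrames inside light dataclass wrappers;
the frame column conventions are documented on each type.  Timestamps are
timezone-naive UTC ``datetime64[ns]`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

VALID_ACTIVITIES = ("transit", "setting", "hauling")
VALID_OP_TYPES = ("setting", "hauling")


def validate_coords(lon, lat) -> None:
    if isinstance(lon, (int, float)) and isinstance(lat, (int, float)):
        # NaN/inf fail the range comparisons too
        if not -90.0 <= lat <= 90.0:
            raise ValueError("latitude outside [-90, 90]")
        if not -180.0 <= lon < 180.0:
            raise ValueError("longitude outside [-180, 180)")
        return
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("non-finite coordinates")
    if np.any(lat < -90) or np.any(lat > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(lon < -180) or np.any(lon >= 180):
        raise ValueError("longitude outside [-180, 180)")


def _check_increasing(ts: pd.Series, what: str) -> None:
    ts = pd.to_datetime(ts)
    if len(ts) > 1 and not ts.is_monotonic_increasing:
        raise ValueError(f"{what}: timestamps not sorted")
    if len(ts) > 1 and ts.duplicated().any():
        raise ValueError(f"{what}: duplicate timestamps")


@dataclass(frozen=True)
class Fix:
    """One timestamped position (lon/lat degrees, WGS84; UTC)."""

    timestamp: pd.Timestamp
    lon: float
    lat: float

    def __post_init__(self):
        validate_coords(self.lon, self.lat)
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))


@dataclass
class BirdTrack:
    """One foraging trip of one bird.

    ``fixes`` columns: timestamp, lon, lat (strictly increasing timestamps).
    """

    bird_id: str
    trip_id: str
    sex: str
    age: int
    year: str
    fixes: pd.DataFrame
    mass_departure: Optional[float] = None
    mass_return: Optional[float] = None

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        self.fixes = self.fixes.reset_index(drop=True)
        _check_increasing(self.fixes["timestamp"], f"trip {self.trip_id}")
        validate_coords(self.fixes["lon"].to_numpy(), self.fixes["lat"].to_numpy())

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class FishingOperation:
    """One line setting or hauling, with endpoint positions."""

    vessel_id: str
    op_type: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    pos_start: Fix
    pos_end: Fix

    def __post_init__(self):
        if self.op_type not in VALID_OP_TYPES:
            raise ValueError(f"op_type must be one of {VALID_OP_TYPES}")
        object.__setattr__(self, "t_start", pd.Timestamp(self.t_start))
        object.__setattr__(self, "t_end", pd.Timestamp(self.t_end))
        if not self.t_start < self.t_end:
            raise ValueError("operation must have t_start < t_end")


def check_ops_disjoint(ops: list) -> None:
    """Operations of one vessel must not overlap in time."""
    by_vessel: dict = {}
    for op in ops:
        by_vessel.setdefault(op.vessel_id, []).append(op)
    for vid, vops in by_vessel.items():
        vops = sorted(vops, key=lambda o: o.t_start)
        for a, b in zip(vops, vops[1:]):
            if b.t_start < a.t_end:
                raise ValueError(f"overlapping operations for vessel {vid}")


@dataclass
class VesselTrack:
    """Regular activity-labeled vessel trajectory.

    ``points`` columns: timestamp, lon, lat, activity (transit|setting|hauling),
    interpolated (bool).  Timestamps lie on a regular grid.
    """

    vessel_id: str
    points: pd.DataFrame

    def __post_init__(self):
        self.points = self.points.reset_index(drop=True)
        _check_increasing(self.points["timestamp"], f"vessel {self.vessel_id}")
        bad = set(self.points["activity"]) - set(VALID_ACTIVITIES)
        if bad:
            raise ValueError(f"unknown activities {bad}")

    def __len__(self) -> int:
        return len(self.points)


# Column convention of the matched-locations frame produced by
# :func:`birdvessel.matching.match_locations` (one row per bird fix):
#
#   bird_id, trip_id, timestamp, lon, lat  -- the bird fix
#   speed_kmh       -- backward-difference ground speed (first fix copies next)
#   is_daylight     -- solar elevation > daylight threshold at the fix
#   vessel_distances -- dict vessel_id -> km for each time-matched vessel
#   n_in_attraction -- number of vessels strictly inside attraction range
#   nearest_vessel_id, nearest_distance_km, nearest_activity
#   in_attraction   -- nearest_distance_km < attraction_km (any vessel)
#   is_attendance   -- in_attraction and nearest < attendance_km and sitting
MATCHED_COLUMNS = [
    "bird_id", "trip_id", "timestamp", "lon", "lat", "speed_kmh",
    "is_daylight", "vessel_distances", "n_in_attraction",
    "nearest_vessel_id", "nearest_distance_km", "nearest_activity",
    "in_attraction", "is_attendance",
]


@dataclass
class EncounterEvent:
    """A maximal tolerated run of in-range bird fixes.

    ``locations`` is the matched-frame slice from the first to the last
    in-range fix of the run, inclusive of tolerated out-of-range fixes.
    """

    trip_id: str
    event_index: int
    locations: pd.DataFrame
    vessel_ids: tuple = ()
    retained_daylight: Optional[bool] = None
    covariates: dict = field(default_factory=dict)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def n_attendance(self) -> int:
        return int(self.locations["is_attendance"].sum())

    @property
    def has_attendance(self) -> bool:
        return self.n_attendance > 0

    @property
    def t_start(self) -> pd.Timestamp:
        return self.locations["timestamp"].iloc[0]

    @property
    def t_end(self) -> pd.Timestamp:
        return self.locations["timestamp"].iloc[-1]
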