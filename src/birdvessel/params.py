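"""Analysis parameters: every threshold of the encounter/attendance pipeline.

All distance thresholds are great-circle kilometres, speeds km/hr, and
sampling intervals minutes.  The defaults encode the study design this
package implements: a 30-km attraction range (the distance at which a
flying albatross can plausibly detect and approach a vessel), a 3-km /
<10 km/hr attendance rule (a bird sitting on the water next to a boat),
a time-to-return tolerance of four consecutive out-of-range fixes
(about one hour at 15-min sampling), and a civil-twilight daylight
boundary at solar elevation -6 degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Colony used by default scenarios: Ile de la Possession, Crozet (46.4S, 51.8E).
DEFAULT_COLONY = (51.8, -46.4)

#: A rectangle of ocean east of the colony standing in for the shelf
#: region where the fleet operates (lon/lat ring, closed implicitly).
#: The colony sits just inside the western edge, so trips cross the shelf
#: on the way out and back while the fleet works clear of the island.
DEFAULT_SHELF = [
    (51.5, -47.2),
    (55.0, -47.2),
    (55.0, -45.6),
    (51.5, -45.6),
]


@dataclass
class AnalysisParams:
    """Single record holding every tunable threshold of the pipeline.

    Attributes
    ----------
    attraction_km : float
        A bird fix is "in attraction range" when strictly closer than this
        to at least one vessel.
    attendance_km : float
        Attendance additionally requires the nearest vessel strictly closer
        than this.  Must be smaller than ``attraction_km``.
    sit_speed_kmh : float
        A bird is "sitting" when its ground speed is strictly below this.
    fly_speed_kmh : float
        A bird is "flying" when its ground speed is strictly above this.
        Fixes exactly at the threshold are neither sitting nor flying.
    time_to_return_locs : int
        Maximum number of consecutive out-of-range bird fixes tolerated
        inside one encounter event before the event is split.
    bird_dt_min : float
        Nominal bird GPS sampling interval (minutes).
    vessel_dt_min : float
        Vessel trajectory grid interval after interpolation (minutes).
    match_tol_min : float
        Maximum |time difference| for the bird-to-vessel nearest-in-time
        join (minutes).
    daylight_elev_deg : float
        Solar elevation above which a fix counts as daylight (degrees;
        -6 is civil twilight).
    earth_radius_km : float
        Sphere radius for great-circle distances.
    shelf_polygon : list of (lon, lat)
        Study-region ring used for on-shelf statistics.
    colony : (lon, lat)
        Central place the simulated trips leave from and return to.
    alpha : float
        Significance level for interaction pruning in the response models.
    nest_mass_loss_rate : float
        Mass-loss rate on the nest (g/day) used to correct weighings taken
        before departure / after return.
    """

    attraction_km: float = 30.0
    attendance_km: float = 3.0
    sit_speed_kmh: float = 10.0
    fly_speed_kmh: float = 10.0
    time_to_return_locs: int = 4
    bird_dt_min: float = 15.0
    vessel_dt_min: float = 10.0
    match_tol_min: float = 5.0
    daylight_elev_deg: float = -6.0
    earth_radius_km: float = 6371.0
    shelf_polygon: list = field(default_factory=lambda: list(DEFAULT_SHELF))
    colony: tuple = DEFAULT_COLONY
    alpha: float = 0.05
    nest_mass_loss_rate: float = 0.0

    def __post_init__(self):
        if not (0 < self.attendance_km < self.attraction_km):
            raise ValueError(
                f"attendance_km ({self.attendance_km}) must be positive and "
                f"smaller than attraction_km ({self.attraction_km})"
            )
        for name in ("sit_speed_kmh", "fly_speed_kmh", "bird_dt_min",
                     "vessel_dt_min", "match_tol_min", "earth_radius_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.time_to_return_locs < 0:
            raise ValueError("time_to_return_locs must be >= 0")
        self.time_to_return_locs = int(self.time_to_return_locs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shelf_polygon"] = [list(p) for p in d["shelf_polygon"]]
        d["colony"] = list(d["colony"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        if "shelf_polygon" in d:
            d["shelf_polygon"] = [tuple(p) for p in d["shelf_polygon"]]
        if "colony" in d:
            d["colony"] = tuple(d["colony"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
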