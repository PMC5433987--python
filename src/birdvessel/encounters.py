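"""Encounter-event segmentation and the daylight-flying event filter.

An encounter event is a maximal run of consecutive bird fixes that remain
within attraction range of at least one vessel, tolerating internal
out-of-range gaps of at most ``time_to_return_locs`` consecutive fixes
(the "time-to-return" rule: a bird allowed to lose sight of a boat for up
to about an hour without the encounter being split).  Events start and
end on in-range fixes; tolerated gap fixes count toward the event length.

Because the birds are visual foragers that rest at night, downstream
analyses keep only events containing at least one daylight flying fix
(speed above the flying threshold while the sun is above civil twilight);
attendance fixes inside retained events count regardless of their own
day/night status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import AnalysisParams
from .types import EncounterEvent


def segment_runs(in_range: np.ndarray, time_to_return: int) -> list[tuple[int, int]]:
    """Index spans (start, end inclusive) of maximal tolerated runs.

    ``in_range`` is a boolean sequence; runs of True are merged across
    internal False gaps of length <= ``time_to_return``.  Spans start and
    end at True positions.
    """
    in_range = np.asarray(in_range, dtype=bool)
    idx = np.flatnonzero(in_range)
    if idx.size == 0:
        return []
    spans = []
    start = prev = idx[0]
    for i in idx[1:]:
        gap = i - prev - 1
        if gap > time_to_return:
            spans.append((int(start), int(prev)))
            start = i
        prev = i
    spans.append((int(start), int(prev)))
    return spans


def segment_encounters(matched: pd.DataFrame,
                       params: AnalysisParams | None = None) -> list[EncounterEvent]:
    """Segment one trip's matched frame into encounter events.

    The frame must be time-ordered and belong to a single trip; events are
    numbered 0..k-1 chronologically within the trip.
    """
    params = params or AnalysisParams()
    if len(matched) == 0:
        return []
    trip_ids = matched["trip_id"].unique()
    if len(trip_ids) != 1:
        raise ValueError("segment_encounters expects a single trip; "
                         "use segment_all for multi-trip frames")
    matched = matched.reset_index(drop=True)
    spans = segment_runs(matched["in_attraction"].to_numpy(),
                         params.time_to_return_locs)
    events = []
    for k, (i0, i1) in enumerate(spans):
        locs = matched.iloc[i0:i1 + 1].reset_index(drop=True)
        in_r = locs["in_attraction"].to_numpy(dtype=bool)
        vids = set()
        for d, ok in zip(locs["vessel_distances"], in_r):
            if ok:
                vids.update(v for v, km in d.items() if km < params.attraction_km)
        events.append(EncounterEvent(
            trip_id=str(trip_ids[0]), event_index=k, locations=locs,
            vessel_ids=tuple(sorted(vids)),
        ))
    return events


def filter_daylight_flying(events: list[EncounterEvent],
                           params: AnalysisParams | None = None) -> list[EncounterEvent]:
    """Set ``retained_daylight`` on each event; returns the same list.

    An event is retained iff it contains at least one fix flying
    (speed strictly above the flying threshold) in daylight.
    """
    params = params or AnalysisParams()
    for ev in events:
        flying = ev.locations["speed_kmh"].to_numpy() > params.fly_speed_kmh
        ev.retained_daylight = bool(
            np.any(flying & ev.locations["is_daylight"].to_numpy(dtype=bool)))
    return events


def segment_all(matched_all: pd.DataFrame,
                params: AnalysisParams | None = None,
                apply_daylight_filter: bool = True) -> list[EncounterEvent]:
    """Segment every trip of a concatenated matched frame."""
    events: list[EncounterEvent] = []
    for _, grp in matched_all.groupby("trip_id", sort=True):
        evs = segment_encounters(grp, params)
        if apply_daylight_filter:
            filter_daylight_flying(evs, params)
        events.extend(evs)
    return events


def retained(events: list[EncounterEvent]) -> list[EncounterEvent]:
    return [e for e in events if e.retained_daylight]
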