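"""End-to-end orchestration: tracks in, events/trip summaries/models out."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .covariates import event_covariates, events_frame, trip_summaries
from .encounters import segment_all
from .matching import match_all
from .models import fit_all, fit_mass_gain
from .params import AnalysisParams
from .types import BirdTrack, FishingOperation, VesselTrack


def year_group_of(year: str, low_boat_years=("2013",)) -> str:
    """Pool years by fleet presence: the low-boat season vs the rest."""
    return "2013" if str(year) in low_boat_years else "2011-12"


def run_pipeline(birds: list[BirdTrack], vessels: list[VesselTrack],
                 ops: list[FishingOperation],
                 params: AnalysisParams | None = None,
                 fit_models: bool = False) -> dict:
    """Match, segment, filter, attach covariates, summarize, (optionally) fit.

    Returns a dict with the matched frame, the event list and frame, trip
    summaries, and model results when requested.
    """
    params = params or AnalysisParams()
    matched = match_all(birds, vessels, params)
    events = segment_all(matched, params, apply_daylight_filter=True)

    meta = pd.DataFrame([{
        "bird_id": b.bird_id, "sex": b.sex, "age": b.age, "year": b.year,
        "mass_departure": b.mass_departure, "mass_return": b.mass_return,
    } for b in birds]).drop_duplicates("bird_id")
    year_by_trip = {b.trip_id: b.year for b in birds}
    for ev in events:
        event_covariates(ev, ops, year_group_of(year_by_trip[ev.trip_id]),
                         params)

    ev_frame = events_frame(events, meta)
    trips = trip_summaries(birds, events, vessels, params)
    out = {"params": params, "matched": matched, "events": events,
           "events_frame": ev_frame, "trips": trips, "birds_meta": meta}
    if fit_models:
        out["models"] = fit_all(trips, ev_frame, alpha=params.alpha)
        try:
            out["models"]["mass_gain"] = fit_mass_gain(meta, trips, params)
        except ValueError as e:
            out["mass_gain_skipped"] = str(e)
    return out


def export_results(result: dict, outdir) -> None:
    """Write events, trip summaries, model terms and a run manifest as text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = result["events_frame"].copy()
    if len(ev):
        ev.to_csv(outdir / "events.csv", index=False)
    result["trips"].to_csv(outdir / "trip_summaries.csv", index=False)
    result["params"].to_yaml(outdir / "params_used.yaml")
    manifest = {"n_trips": len(result["trips"]),
                "n_events": len(result["events"]),
                "models": {}}
    for name, mr in result.get("models", {}).items():
        mr.terms.to_csv(outdir / f"model_{name}.csv", index=False)
        manifest["models"][name] = mr.manifest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
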