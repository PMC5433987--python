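"""Activity covariates, attendance metrics, and trip summaries."""

import numpy as np
import pandas as pd
import pytest

from birdvessel.covariates import (attendance_metrics, boats_on_shelf_at,
                                   prop_fishing, time_to_fishing_hr,
                                   trip_summary)
from birdvessel.geo import haversine_km
from birdvessel.params import AnalysisParams
from birdvessel.types import EncounterEvent, FishingOperation, Fix


def _op(vid, t0, t1, op_type="hauling"):
    t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
    return FishingOperation(vessel_id=vid, op_type=op_type, t_start=t0,
                            t_end=t1, pos_start=Fix(t0, 52.0, -46.0),
                            pos_end=Fix(t1, 52.1, -46.1))


class TestTimeToFishing:
    def test_zero_when_fishing_at_encounter_start(self):
        ops = [_op("V1", "2012-02-05 08:00", "2012-02-05 12:00")]
        assert time_to_fishing_hr("2012-02-05 09:00", ops, {"V1"}) == 0.0

    def test_half_hour_when_operation_ended_30min_before(self):
        ops = [_op("V1", "2012-02-05 04:00", "2012-02-05 08:30"),
               _op("V1", "2012-02-05 14:00", "2012-02-05 18:00",
                   "setting")]
        assert time_to_fishing_hr("2012-02-05 09:00", ops,
                                  {"V1"}) == pytest.approx(0.5)

    def test_half_hour_when_operation_starts_30min_after(self):
        ops = [_op("V1", "2012-02-05 09:30", "2012-02-05 12:00")]
        assert time_to_fishing_hr("2012-02-05 09:00", ops,
                                  {"V1"}) == pytest.approx(0.5)

    def test_missing_when_vessels_have_no_operations(self):
        ops = [_op("V9", "2012-02-05 08:00", "2012-02-05 12:00")]
        assert np.isnan(time_to_fishing_hr("2012-02-05 09:00", ops, {"V1"}))

    def test_minimum_across_the_events_vessels(self):
        ops = [_op("V1", "2012-02-05 02:00", "2012-02-05 05:00"),
               _op("V2", "2012-02-05 10:00", "2012-02-05 12:00")]
        # V1 ended 4 hr before; V2 starts 1 hr after -> 1 hr
        assert time_to_fishing_hr("2012-02-05 09:00", ops,
                                  {"V1", "V2"}) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_boundary_scan(self, seed):
        rng = np.random.default_rng(seed)
        t0 = pd.Timestamp("2012-02-05")
        ops = []
        cursor = t0
        for k in range(8):
            cursor += pd.Timedelta(minutes=int(rng.integers(30, 300)))
            end = cursor + pd.Timedelta(minutes=int(rng.integers(30, 240)))
            ops.append(_op(f"V{k % 3 + 1}", cursor, end,
                           "setting" if k % 2 else "hauling"))
            cursor = end
        vids = {"V1", "V2"}
        for _ in range(40):
            t = t0 + pd.Timedelta(minutes=int(rng.integers(0, 4000)))
            got = time_to_fishing_hr(t, ops, vids)
            # oracle: scan every boundary of every relevant operation
            best = np.inf
            for op in ops:
                if op.vessel_id not in vids:
                    continue
                if op.t_start <= t <= op.t_end:
                    best = 0.0
                    break
                best = min(best,
                           abs((t - op.t_end).total_seconds()) / 3600
                           if t > op.t_end else
                           abs((op.t_start - t).total_seconds()) / 3600)
            assert got == pytest.approx(best)


def _event(activities, distances=None, attendance=None, speeds=None):
    n = len(activities)
    distances = distances if distances is not None else [2.0] * n
    attendance = attendance if attendance is not None else [False] * n
    locs = pd.DataFrame({
        "bird_id": "B1", "trip_id": "T1",
        "timestamp": pd.date_range("2012-02-05 08:00", periods=n,
                                   freq="15min"),
        "in_attraction": True, "is_attendance": attendance,
        "nearest_activity": activities,
        "nearest_distance_km": distances,
        "speed_kmh": speeds if speeds is not None else [30.0] * n,
        "is_daylight": True, "n_in_attraction": 1,
        "nearest_vessel_id": "V1",
        "vessel_distances": [{"V1": d} for d in distances]})
    return EncounterEvent(trip_id="T1", event_index=0, locations=locs,
                          vessel_ids=("V1",))


class TestPropFishing:
    def test_transit_throughout_is_zero(self):
        assert prop_fishing(_event(["transit"] * 6)) == 0.0

    def test_hauling_throughout_is_one(self):
        assert prop_fishing(_event(["hauling"] * 6)) == 1.0

    def test_seven_of_fourteen_is_half(self):
        acts = ["hauling"] * 7 + ["transit"] * 7
        assert prop_fishing(_event(acts)) == pytest.approx(0.5)


class TestAttendanceMetrics:
    def test_four_attendance_fixes_at_15min_is_one_hour(self, params):
        ev = _event(["hauling"] * 10,
                    attendance=[True] * 4 + [False] * 6,
                    distances=[1.0] * 10)
        m = attendance_metrics(ev, params)
        assert m["duration_locs"] == 4
        assert m["duration_hr"] == pytest.approx(1.0)
        assert m["prop_of_event"] == pytest.approx(0.4)
        assert m["mean_distance_m"] == pytest.approx(1000.0)

    def test_requires_attendance(self, params):
        with pytest.raises(ValueError, match="attendance"):
            attendance_metrics(_event(["transit"] * 3), params)

    def test_mean_distance_below_attendance_range(self, small_result,
                                                  params):
        for ev in small_result["events"]:
            if ev.has_attendance:
                m = attendance_metrics(ev, params)
                assert 0 < m["prop_of_event"] <= 1
                assert m["mean_distance_m"] < params.attendance_km * 1000


class TestTripSummary:
    def test_zero_vessels(self, small_scenario, params):
        cfg, sc = small_scenario
        bird = sc["birds"][0]
        s = trip_summary(bird, [], [], params)
        assert s["avg_boats_present"] == 0.0
        assert s["n_encounters"] == 0
        assert not s["any_attendance"]
        assert 0 <= s["prop_on_shelf"] <= 1

    def test_attendance_time_is_sum_over_retained_events(self, small_result,
                                                         params):
        trips = small_result["trips"]
        ev = small_result["events_frame"]
        for _, row in trips.iterrows():
            sub = ev[(ev["trip_id"] == row["trip_id"])
                     & ev["retained_daylight"]]
            expect = sub["n_attendance"].sum() * params.bird_dt_min / 60.0
            assert row["attendance_time_hr"] == pytest.approx(expect)
            assert row["n_encounters"] == len(sub)

    def test_avg_boats_matches_bruteforce_recount(self, small_scenario,
                                                  params):
        from shapely.geometry import Point, Polygon
        cfg, sc = small_scenario
        bird = sc["birds"][0]
        vessels = sc["vessel_tracks"]
        ts = bird.fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
        got = boats_on_shelf_at(ts, vessels, params)
        poly = Polygon(params.shelf_polygon)
        tol = pd.Timedelta(minutes=params.match_tol_min)
        for i, t in enumerate(bird.fixes["timestamp"][::37]):
            count = 0
            for vt in vessels:
                pts = vt.points
                dt = (pts["timestamp"] - t).abs()
                j = dt.idxmin()
                if dt[j] <= tol and poly.covers(
                        Point(pts["lon"][j], pts["lat"][j])):
                    count += 1
            assert got[::37][i] == count

    def test_total_distance_is_great_circle_segment_sum(self, small_scenario,
                                                        params):
        cfg, sc = small_scenario
        bird = sc["birds"][1]
        s = trip_summary(bird, [], [], params)
        f = bird.fixes
        expect = sum(
            haversine_km(f["lon"].iloc[i], f["lat"].iloc[i],
                         f["lon"].iloc[i + 1], f["lat"].iloc[i + 1])
            for i in range(len(f) - 1))
        assert s["total_distance_km"] == pytest.approx(expect, rel=1e-9)


def test_population_activity_shares_sum_to_one(small_result):
    """Attendance fixes split by vessel activity class partition the total."""
    m = small_result["matched"]
    att = m[m["is_attendance"]]
    if len(att) == 0:
        pytest.skip("scenario produced no attendance fixes")
    shares = att["nearest_activity"].value_counts(normalize=True)
    assert shares.sum() == pytest.approx(1.0)
    assert set(shares.index) <= {"setting", "hauling", "transit"}
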