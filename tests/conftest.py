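import numpy as np
import pandas as pd
import pytest

from birdvessel import (AnalysisParams, ScenarioConfig, two_encounter_fixture,
                        match_all, run_pipeline, simulate_scenario)


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def worked_example(params):
    return two_encounter_fixture(params)


@pytest.fixture(scope="session")
def small_scenario():
    """One modest scenario shared by the slower integration tests."""
    cfg = ScenarioConfig(n_birds=10, season_days=14,
                         trip_duration_range=(2.0, 7.0), seed=11)
    return cfg, simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_result(small_scenario):
    cfg, sc = small_scenario
    return run_pipeline(sc["birds"], sc["vessel_tracks"], sc["ops"])


@pytest.fixture(scope="session")
def small_matched(small_result):
    return small_result["matched"]


def brute_force_runs(in_range, time_to_return):
    """Reference segmentation: enumerate all maximal tolerated runs.

    A tolerated run is a maximal index interval [i, j] with in_range[i]
    and in_range[j] true and no internal gap of consecutive false longer
    than time_to_return.  Enumerated directly from the definition, O(n^2).
    """
    in_range = list(in_range)
    n = len(in_range)

    def valid(i, j):
        if not (in_range[i] and in_range[j]):
            return False
        gap = 0
        for k in range(i, j + 1):
            gap = 0 if in_range[k] else gap + 1
            if gap > time_to_return:
                return False
        return True

    spans = []
    for i in range(n):
        for j in range(i, n):
            if valid(i, j):
                # maximal: no valid extension on either side
                if any(valid(i2, j) for i2 in range(i)):
                    continue
                if any(valid(i, j2) for j2 in range(j + 1, n)):
                    continue
                spans.append((i, j))
    # keep only maximal spans (drop spans contained in another)
    out = [s for s in spans
           if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)]
    return sorted(set(out))
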