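# Methods

This note documents the models and conventions the package implements,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot validate.

## Geometry and time

All distances are great-circle (haversine, R = 6371 km); no map
projection is used anywhere. At the scales that drive the analysis
(attendance within 3 km, attraction within 30 km) the spherical
approximation errs by far less than GPS noise, and staying on the sphere
keeps every contract projection-free. Timestamps are UTC throughout;
local time never enters the computation — day and night come from solar
elevation at the fix, not from clock time.

A fix's ground speed is the backward difference: distance from the
previous fix divided by elapsed time. The first fix of a trip copies the
following segment's speed. Attendance is a state *at* a location, and the
backward difference uses only past information, which is the convention
most tracking pipelines follow. All behavioral thresholds are strict
inequalities: sitting is speed < 10 km/hr, flying is speed > 10 km/hr,
in-range is distance < 30 km, attendance distance < 3 km. A fix exactly
at a threshold is therefore neither sitting nor flying; with real-valued
positions this is a measure-zero event, but the convention matters for
constructed test cases.

Solar elevation uses the NOAA solar calculator's truncated-series
ephemeris with the standard atmospheric refraction correction; agreement
with an independently coded Astronomical Almanac implementation
(Michalsky's algorithm) is within 0.05° over the study years, against a
classification threshold of −6° (civil twilight). Daylight is elevation
strictly above the threshold.

## Vessel trajectory reconstruction

VMS fixes (hourly) and operation endpoints are merged per vessel into one
knot sequence — on an exact timestamp collision the operation endpoint
wins, being a dedicated reading — and linearly interpolated in lon/lat
onto a 10-min grid aligned to whole UTC 10-min boundaries. Linear (not
great-circle) interpolation between knots is deliberate: at ≤1-hr gaps
and working-vessel speeds the difference is meters. The grid never
extrapolates: outside its track span a vessel is absent, and bird fixes
there simply match nothing. Grid points coinciding with source knots pass
through bit-identically and are flagged non-interpolated. Activity labels
(`setting`/`hauling`, boundaries inclusive) apply exactly inside declared
operation intervals; everything else is `transit`. Operations are taken
as given; no fishing-from-movement inference is attempted.

## Matching and classification

For each bird fix and each vessel, the vessel grid point minimizing |Δt|
subject to |Δt| ≤ 5 min is selected; a tie at exactly 5 min on both sides
goes to the earlier point, for determinism. With a 10-min vessel grid the
tolerance is always satisfiable inside the span. In-range status uses
*any* matched vessel; attendance statistics use the nearest vessel only.
When several vessels are exactly equidistant the lexicographically
smallest vessel id wins. Bird positions are never interpolated — the join
is nearest-in-time only.

## Encounter events

An encounter event is a maximal run of consecutive in-range fixes,
merging across internal out-of-range gaps of at most `time_to_return_locs`
consecutive fixes (default 4 ≈ 1 hr at 15-min sampling). The gap is
counted in fixes, not minutes, matching the sampling-based definition;
irregular sampling should be caught upstream. Events are trimmed to start
and end on in-range fixes; tolerated gap fixes count toward the event
length. An event's vessel set contains every vessel within range at any
of its in-range fixes; events are never split per vessel.

Events are retained for analysis only if they contain at least one fix
flying in daylight — the birds are visual foragers that rest at night, so
an encounter with no daylight flying cannot reflect a detection decision.
Attendance fixes inside retained events count regardless of their own
day/night status.

Two segmentation properties are theorems, and are asserted per dataset in
the tests: the event count is non-increasing in the time-to-return
tolerance, and the in-range fix count is non-increasing in the attraction
radius. The third headline property — per-encounter attendance
probability rises as the radius tightens — is a strong statistical
tendency, *not* an invariant: shrinking the radius can split one attended
event into an attended and an unattended fragment, briefly lowering the
fraction in one dataset. The test suite therefore checks it on the pooled
encounters of an ensemble of simulated datasets, where it is cleanly
monotone, and the sensitivity sweep reports per-cell values for the user
to inspect.

## Covariates

`time_to_fishing` is the time from encounter start to the nearest fishing
activity of the event's vessels: 0 when a vessel is mid-operation at the
start, otherwise the minimum of time-since-last-op-end and
time-to-next-op-start; missing (and the event dropped from the
attendance-probability model) when those vessels have no operations on
record. `prop_fishing` is the share of the event's fixes whose nearest
vessel is in operation. "Boats present" during a trip is evaluated at the
trip's own fix instants — a vessel counts when it has an on-shelf track
point within the match tolerance — which is simple, reproducible, and
within rounding of any hourly average. The shelf is a user-supplied
polygon with on-boundary counted as inside.

## Response models

| response | family | offset | random terms |
|---|---|---|---|
| encounters per trip | negative binomial | log trip days | bird |
| attendance at encounter | binomial | — | bird, trip |
| attendance fixes per encounter | negative binomial | — | bird, trip |
| attendance share of encounter | negative binomial | log event fixes | bird, trip |
| mean attendance distance (m) | gaussian | — | bird, trip |
| mass gain at sea (g) | gaussian | — | none |

Count responses are modeled as numbers of fixes rather than hours: the
distributions are zero-skewed and Poisson-like, and the negative binomial
absorbs the overdispersion. Age and sex and their interaction enter every
model; the encounter-rate model adds mean fleet presence, while the
encounter-level models instead add a year grouping (seasons pooled by
fleet presence: birds can plausibly know the year's conditions, not the
instantaneous boat count), its interactions with age and sex, the mean
number of vessels in range, and the activity covariate
(`time_to_fishing` for attendance probability, `prop_fishing` for the
three attendance-behavior models).

Interaction pruning is sequential and worst-first: fit, find the least
significant first-order interaction with p > α (default 0.05), remove it,
refit, repeat. Main effects and random terms are never removed. Pruning
is invariant to row order. For Gaussian mixed models the pruning p-values
come from likelihood-ratio tests (ML, not REML); elsewhere from Wald
statistics.

Estimation engines, in order of preference per family:

* **Gaussian:** `statsmodels` MixedLM with a random bird intercept and a
  trip-within-bird variance component (trips are nested in birds here, so
  "bird and trip intercepts" and the nested parameterization coincide).
  If the mixed fit fails to converge the model refits as OLS with
  cluster-robust standard errors on bird, flagged in the result notes.
* **Binomial:** `lme4::glmer` via Rscript. A variational-Bayes fit
  (statsmodels) is the fallback when R is unavailable; its point
  estimates match glmer closely but its posterior SDs are optimistic,
  which the result notes say explicitly.
* **Negative binomial:** no mixed NB engine exists in the Python stack,
  so these responses are fitted by full ML without random terms and
  inference uses cluster-robust standard errors clustered on bird —
  clusters coincide with the grouping structure, so the SEs absorb the
  dependence the intercepts would have modeled. If the ML dispersion
  estimate is on the boundary (singular Hessian), the fallback fits
  Poisson by IRLS, estimates the dispersion by the Cameron–Trivedi
  auxiliary regression, and refits a fixed-dispersion NB GLM.

The mass-gain model is a plain linear model (one record per weighed bird;
the fit refuses duplicated birds or fewer than two weighed birds per
sex): mass gain ~ year + sex × attendance share of trip + departure-mass
anomaly. Departure mass enters as the within-sex anomaly so the strong
sexual size dimorphism cannot masquerade as a departure-mass effect.
Weighings taken on the nest are projected to the moments of departure and
return with a configurable nest mass-loss rate (g/day, default 0 — the
correction is the user's responsibility when the rate is known).

## Synthetic data

The generator reproduces the *structure* the pipeline consumes, with
interaction behavior programmed so recovery tests have ground truth:

* **Fleet:** 0–7 vessels (default 3) on slow correlated random walks
  (3–6 km/hr) inside the shelf polygon, kept ≥60 km from the colony;
  hourly VMS; one line setting per night (start strictly below civil
  twilight) and one hauling per day, endpoints taken from the vessel's
  own path so merged trajectories are self-consistent.
* **Birds:** central-place trips at exact 15-min sampling, duration
  lognormal (median 8 days) clipped to a configurable 2–29-day range,
  departing and returning within a few km of the colony. Movement
  alternates flight (20–80 km/hr) and sitting (0–5 km/hr) — both bands
  deliberately clear of the 10 km/hr boundary so classification is
  unambiguous in tests.
* **Interactions:** on entering attraction range of any vessel a bird
  attends with probability `p_attend_given_encounter` (default 0.6); if
  attending it closes on the vessel and sits beside it (offset 0.3–2.2 km)
  for a geometric number of fixes (mean 17 ≈ 4.25 hr), then leaves;
  otherwise it flies through and away. Every encounter and bout is logged.
  During the forced end-of-trip return leg a bird flies straight home;
  range entries on that leg are logged as non-attended encounters.
* **Reproducibility:** one scenario seed; vessel and bird sub-streams are
  spawned at fixed offsets, so adding vessels never perturbs bird draws
  and identical configurations are bit-identical.

Default interaction parameters (attendance probability 0.6, bout mean
≈4.25 hr, offsets averaging ≈1.25 km) sit at the magnitudes this kind of
fishery-attendance system exhibits, so simulated summaries land in a
realistic range. What the generator does **not** emulate: wind and
weather, energetics, memory or individual site fidelity, GPS measurement
error, device failure gaps, or behavioral states beyond
fly/sit/attend. Passing recovery tests therefore demonstrates that the
pipeline measures what the generator programmed — encounter counts,
attendance probabilities, bout statistics — not that real albatrosses
behave like the generator.

Test problem sizes were chosen to keep the full suite fast while leaving
the estimators well-identified: the shared integration scenario uses 10
trips over 14 days with 3 vessels; the monotonicity ensemble uses 20
two-bird scenarios; the probability-recovery scenario uses 50 trips
(~330 programmed encounters); slope recovery uses 2000 events from 100
birds × 4 trips.

## Known limitations

* The negative-binomial models do not carry literal random intercepts
  (cluster-robust inference instead); variance components for those
  responses are not reported.
* Variational binomial fallback underestimates standard errors; results
  carry a note when it was used.
* The time-to-return gap is counted in fixes; tracks with irregular
  sampling should be regularized or filtered upstream.
* Linear lon/lat interpolation of vessel tracks assumes sub-hourly knot
  spacing; it is not suitable for multi-hour VMS gaps near the poles.
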