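# Methods

This note documents the models, rules and defaults the package implements,
the design choices made where several readings were defensible, and what the
synthetic-data generator does and does not emulate.

## Data model and time handling

All sensor streams share a long-format schema: `participant_id`,
`device_id`, `timestamp_utc` (ISO-8601 with offset), `tz`, then
sensor-specific payload columns. Categorical payloads have closed
vocabularies (call type ∈ {incoming, outgoing, missed}; screen status ∈
{on, off, lock, unlock}; actigraph status ∈ {active, rest, sleep}; bed
occupancy ∈ {occupied, free}); readers normalize case/whitespace and reject
anything else. Exact duplicate rows are dropped with a logged count — the
minimal defensible stand-in for de-duplicating repeated uploads.

Behavior is organized by the local clock, so every binning step runs in a
single configurable study timezone (default `Europe/Helsinki`), resolved by
the zone's rules including DST. Days are midnight-to-midnight local; hour
bins are half-open `[h, h+1)`; hour-of-week is `weekday*24 + hour` with
Monday 00:00 = 0. Per-participant timezones are out of scope.

## Preprocessing rules

Applied per participant, in order:

1. **First/last day trim** — all rows on the first and last observed local
   date are dropped (incomplete capture at the boundaries).
2. **8-week restriction** — rhythm and volume analyses keep each
   participant's first 56 calendar days after trimming; participants whose
   observed span is shorter are excluded from those analyses and reported.
   "8 weeks of data" is read as calendar span, not days-with-data.
3. **App-session sanity filter** — foreground sessions longer than 10 hours
   are removed (strictly greater: exactly 10 h survives); negative durations
   are invalid and removed. Removal counts land in the run manifest.
4. **Screen sessions** — a use episode starts at an `on`/`unlock` event and
   ends at the participant's next `off`/`lock`; sessions are capped at 2 h
   as a guard against missing end events (cap count logged). This pairing is
   a documented stand-in: the upstream definition of "total screen time" is
   not specified.

Counts/durations are aggregated per participant × local date × hour. Hours
with no events are absent (implicitly zero) for daily means, but the
168-bin rhythm vector is defined over all bins, so empty bins are true
zeros there. Sample SD (ddof=1) is used throughout.

Accelerometer: magnitude = √(x²+y²+z²), centered by subtracting the
participant's overall mean magnitude; the hourly SD of centered magnitude is
the physical-activity proxy; hours with <2 samples are missing.

## Sleep scoring

A night spans local noon→next noon and is attributed to its starting date,
so sleep is never split at midnight (the night-window convention is ours;
the source rules are stated per "day"). Rules:

* **bedtime** — start of the first run of ≥3 consecutive minutes of `sleep`
  epochs (≥6 epochs at 30 s);
* **waketime** — start of the first ≥3-minute run of `active` epochs after
  bedtime within the same night window (the calendar-day wording of the wake
  rule is ambiguous; anchoring after bedtime is the reading that cannot
  produce wake-before-bed);
* **bed sensor** — the sleep period is the longest maximal `occupied` run;
  equal-length runs tie-break to the earlier one (deterministic);
* a gap of >5 minutes between consecutive epochs breaks any run, so missing
  data cannot fabricate continuity;
* per participant the first and last scored nights are dropped, and nights
  with duration <3 h or >13 h are omitted — both bounds strict, so exactly
  3 h / 13 h survive. The filtered output carries a hard assertion that all
  surviving durations lie in [3, 13] h.

Device-internal epoch scoring (actigraph sleep/wake algorithm, bed-sensor
occupancy derivation) is consumed as given, not re-implemented.

## Mobility features

The upstream feature definitions live in unavailable supplementary material,
so every threshold here is a package default, exposed as a config key
(`MobilityConfig`):

* accuracy filter 100 m; downsampling to one fix per 10-minute bin (median
  lat/lon); stationarity if speed <1 m/s, or displacement <100 m when speed
  is absent; days with <6 binned fixes yield no features;
* significant places: DBSCAN over each participant's stationary fixes,
  haversine radius 100 m, min 5 fixes; noise fixes are transient;
* log location variance = ln(var(lat)+var(lon)) (sample variance, squared
  degrees; 1e-12 floor inside the log). Natural log matches the magnitude of
  group means around −10 to −12 for degree-scale variances;
* entropy H = −Σ p&#8342; ln p&#8342; over the day's time fractions per significant
  place. Both raw H and H/ln(K) are emitted, where K is the participant's
  total place count: published "normalized entropy" values above 1 suggest
  the unnormalized quantity, so both are labeled explicitly. Normalizing by
  the participant-level K makes the statistic comparable across days within
  a person — an assumption, flagged as such;
* home = the place holding most 00:00–06:00 fixes across the span;
  distance = summed haversine distances between consecutive binned fixes;
* weekday (Mon–Fri) and weekend (Sat–Sun) features are summarized
  separately; public holidays are ignored.

## Rhythms and homogeneity

Weekly rhythms are the event totals per hour-of-week over the 8-week
window, normalized to sum to 1; all-zero streams are flagged and excluded
from distance analyses (cosine distance is undefined for them, and their
count is logged). Intradifference uses unordered pairs (i<j) only —
self-pairs or duplicated pairs would merely rescale ranks.

The MWU statistic is U = #{(i,j): x&#7522; > y&#11388;} + ½·#ties. For combined
n ≤ 16 the two-sided P is exact: all C(n, n&#8339;) assignments of the pooled
values are enumerated and assignments with |U − mn/2| at least the observed
deviation are counted. Larger samples use the tie-corrected normal
approximation with a 0.5 continuity correction. The BH step-up adjustment
preserves input order and caps at 1. Both are cross-checked in the test
suite against brute-force oracles and against scipy/statsmodels.

The BH family is the set of activity types tested in one report
invocation. A caveat carried over from the source procedure: pairwise
distances within a group share individuals and are not independent, so the
MWU P values on distance multisets are descriptive rather than exact; the
analysis replicates the published procedure as printed.

Figure-style summaries sum rhythm weights over four local-hour regions —
night 0–6, morning 6–12, afternoon 12–18, evening 18–24 (the labeled
6-hour regions are used; some published captions call them 4-hour bins).

## Adherence and missingness

A participant is adherent in a 14-day period if they answered ≥1 PHQ-9 in
it; period clocks start at each participant's own enrollment date (rolling
enrollment). Intermittent gaps do not terminate participation: survival time
runs to the last answered period. Event semantics (our minimal consistent
reading, since the published survival analysis does not define the event): a
last response before the participant's final possible period is a dropout
event; a response in the final period is administratively censored.
Kaplan-Meier estimation and the k-group log-rank test delegate to lifelines;
with no censoring the KM curve equals the empirical survival function
(asserted in tests). Passive-data missingness counts enrolled local dates
with zero battery rows, averaged per participant and then per group.

## Association models

Windows are the 14 local dates preceding each PHQ-9 date (the response day
excluded); features average over days with data, with per-feature coverage
counts and a low-coverage flag below 4 days. Duration predictors are
within-person centered (`_W`); count predictors enter raw, following the
published table's suffix pattern literally. Missing predictors drop the
window listwise for that model only. The model is a random-intercept-only
REML fit (no random slopes — only the grouping factor is specified
upstream); group membership is not a covariate by default (a config choice,
as the published models' covariate set is unstated); CIs are Wald (the CI
type is likewise unstated). Non-convergence retries lbfgs → bfgs → powell
before reporting failure. Duration units are minutes.

## Synthetic-data generator

The generator defines the study conditions for all recovery tests:

* **cohort** — four groups (control, MDD, BD, BPD); control demographics
  mean age 42 (SD 14.07), 77% female, 83% full-time employed; patients 34.7
  (SD 12.71), 71.1% female, 9.9% full-time. Baseline PHQ-9 means 1.7 /
  14.6 / 13.53 / 14.57 (control/MDD/BD/BPD). Rolling enrollment over 90
  days; follow-up capped at 365 days.
* **dropout** — geometric on 14-day period boundaries with per-group hazard
  solving (1−h)⁴ = week-8 adherence (0.52, 0.739, 0.833, 0.50 for
  control/MDD/BD/BPD → h ≈ 0.151, 0.073, 0.045, 0.159).
* **events** — calls/SMS/screen/app times from an inhomogeneous Poisson
  process whose hour-of-week intensity is the group's template (controls:
  afternoon peak, strong weekend dip; patients: late-morning shift, flat
  weekends) times per-person multiplicative log-normal noise. 15% of calls
  are missed with zero duration, so ~85% of calls have positive duration,
  matching the observed answered-call share; nonzero durations are
  log-normal (median ≈55 s). Daily base rates (2.5 calls, 2.5 SMS, 45
  screen sessions, 30 app sessions) are pragmatic choices — the empirical
  inter-event distributions are not published.
* **GPS** — anchor-place mixture (home/work/other with Gaussian jitter);
  controls commute to work with p=0.8 on weekday work hours, patients 0.15,
  planting the lower patient location variance/entropy.
* **accelerometer** — 30-s samples with time-of-day-dependent magnitude SD;
  **actigraph** — 30-s two-state daily schedule (sleep ~23:00–07:00 with
  30-min jitter, rest margins, configurable status-flip noise);
  **bed** — 1-s occupancy epochs around the scheduled sleep window;
  **battery** — 4-hourly pings except on missing days (group rates 1.2%,
  14.1%, 4.5%, 20.4% for control/MDD/BD/BPD).
* **PHQ-9** — score = clip(round(baseline + Σ β·centered-feature +
  b&#7522; + ε), 0, 27) per 14-day period while enrolled; default planted β:
  incoming-call duration −0.08/min, outgoing +0.05/min, morning magnitude
  SD −2.05; intercept SD 2, residual SD 3.
* **reproducibility** — one master seed; per-participant per-sensor
  sub-seeds from a stable hash, so regenerating one sensor never perturbs
  another; identical config+seed yields byte-identical outputs. Event times
  are generated on the local clock and stored as UTC+zone.

`simulate_association_windows` and `simulate_rhythm_cohort` generate
window-level and rhythm-level data directly at the stated study conditions
(100 participants × 12 windows; 30 per group), which is how the recovery
studies reach 100 replications quickly; the full stream→feature→fit path is
exercised end to end at smaller n in the test suite.

What the generator does **not** emulate: physiological bed-sensor channels
(heart rate, HRV, respiration), EMA prompts, per-participant timezones or
travel, device clock skew, Wi-Fi positioning, and realistic app-catalog
diversity. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under the planted model, not validity of the behavioral
assumptions on real cohorts.

## Numerical choices and degenerate inputs

* Sample SD (ddof=1) everywhere; cosine distances clipped to [0,1] against
  float fuzz; log-variance floor 1e-12; MWU exact-path tie comparison uses a
  1e-12 slack so observed-deviation equality counts as "at least as extreme".
* Zero-duration calls count toward call counts but contribute 0 minutes to
  duration features.
* Constant-response mixed models short-circuit to β=0 with zero variance
  components rather than exercising a degenerate optimizer.
* DBSCAN clustering is deterministic after canonical sorting of fixes.

## Known limitations

* The published group means, P values and coefficient table are not
  reproducible — the underlying data are not available — so validation is
  structural (in-study arithmetic identities) and statistical (oracle
  agreement, calibration, planted-effect recovery) rather than numerical
  replication.
* Screen-session duration and every GPS threshold are documented
  assumptions standing in for unavailable upstream definitions.
* The homogeneity MWU inherits the pairwise-dependence caveat above.
* Mixed-model CI coverage is nominal-Wald; small-sample coverage runs
  slightly below 95% (observed ≈92/100 at 100 participants × 12 windows).
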