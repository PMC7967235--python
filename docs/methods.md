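# Methods

## Data model

The pipeline consumes four timestamped channels per patient, all plain CSV
with ISO 8601 timestamps in a single patient-local clock (no DST
arithmetic; streams are at most a few weeks long):

* `accel.csv` — one row per minute: step count, mean accelerations
  `ax, ay, az` (g), posture angle `theta_deg`. The patch calibrates its
  x-axis along the longitudinal body axis, so if `theta_deg` is absent it
  is derived as θ = |asin(a_x / ‖a‖)| in degrees; angles are canonicalized
  so 0° means lying/horizontal and 90° upright.
* `hr.csv` — mean heart rate every 5 minutes. Heart rate enters only the
  interval analyzability check; no heart-rate analytics are performed.
* `pairing.csv` — spans during which the patch was pairing with the phone
  (its sampling is unreliable then).
* `ingestions.csv` — one timestamp per recorded dose event. Multiple
  events on one calendar day collapse to the earliest; the regimen is
  assumed once daily.

Patients with fewer than 7 distinct days of patch data are excluded from
cohort metrics: per-patient z-scores and clustering need a baseline of
typical days to be meaningful.

## Interval labeling

Days are cut into 15-minute, half-open `[start, start+15)` intervals. The
day boundary defaults to **noon** so that one night's sleep lies inside a
single day window; the label of a day is the calendar date on which its
window starts. Midnight would split every night in two; any boundary
clock time is configurable.

An interval is analyzable iff (1) no pairing span intersects it (any
non-zero overlap disqualifies), (2) it holds ≥ 10 accelerometer records,
and (3) ≥ 2 heart-rate records. Non-analyzable intervals are MISSING. A
minute is a rest minute iff θ < 30° **strictly**; an analyzable interval
is REST iff rest minutes / collected records > 0.70 **strictly** (14 of 20
records, exactly 70%, is ACTIVE). The denominator is the number of records
actually collected (10–15), not the nominal 15, so sparsely sampled but
analyzable intervals are not penalized.

## Longest rest period

The longest continuous rest period (LCRP) is the maximal run of REST
intervals, earliest run on ties. It is then extended outward, one side at
a time, until neither side grows:

* scan up to 5 intervals beyond the current edge for the nearest REST run;
* if every intervening interval is MISSING, annex the run (a data gap is
  not evidence that rest ended);
* if exactly one intervening interval is ACTIVE — a brief awakening —
  annex only a run of ≥ 4 consecutive REST intervals;
* if two or more are ACTIVE, stop that side.

The scan restarts from the new edge after each annexation, so chains of
runs separated by small gaps are absorbed iteratively; a single-pass
variant is available (`iterative_extension=false`) for sensitivity
analysis. The two-active case sits between the stated "exactly one" and
"more than two" branches; blocking at ≥ 2 is the conservative choice and
is exposed as `two_active_blocks` (set it false to block only at ≥ 3).
Bridged MISSING/ACTIVE intervals count toward the period's duration but
contribute no quality windows. Days with no REST interval have no rest
period and are dropped from downstream scoring.

An independent run-length-encoded rule-table implementation of the same
rules lives in the test suite; the two code paths agree on an exhaustive
enumeration of all 797,160 state sequences of length ≤ 12.

## Window features

Within each scored interval, 3-minute rolling windows (stride one minute,
never crossing an interval boundary) give up to 13 points. Windows
overlapping an empty minute slot are dropped, not imputed. Four features
summarise a window:

| feature | definition | units | behaviour |
|---|---|---|---|
| `yz_circ_dev` | mean |√(a_y²+a_z²) − 1| | g | ~0 lying still; grows with movement/uprightness |
| `theta_mean` | mean θ | deg | 0 horizontal, 90 upright |
| `accel_norm_mean` | mean ‖a‖ | g | 1 at rest; >1 with movement |
| `ax_sd` | σ(a_x), population (n) denominator | g | 0 when still |

The circular deviation is formalized as deviation of the y–z magnitude
from the 1-g circle: while lying, gravity lives almost entirely in the
y–z plane of the torso patch, so the (a_y, a_z) vector sits on the unit
circle and the deviation is near zero. The angular-statistics alternative
(circular dispersion of atan2(a_z, a_y)) is kept in the candidate
registry as a distinct feature. The SD feature uses the population
denominator over its 3 points (`sd_ddof_feature=0`); with n = 3 the
choice is material and is config-exposed.

A registry of ~35 documented rolling-window statistics (per-axis and
posture means/SDs/ranges/RMS, norm and y–z-magnitude statistics, circular
dispersion, step statistics) supports an optional selection path:
per-patient hierarchical feature merging (distance 1 − |Pearson r|,
average linkage) into k clusters, cross-patient co-assignment consensus,
and one representative per consensus group. The default pipeline uses
the four canonical features without selection; the registry's formulas
are standard actimetry statistics, not reconstructions of any particular
historical candidate set.

## Rest quality

All scored windows of a patient (by default the windows inside that
patient's rest periods; `fit_scope="all-windows"` fits on every analyzable
interval instead) are min–max normalised per feature to the patient's own
range — a zero-range feature maps to 0 with a logged warning — and
clustered with k-means, k = 2, `kmeans_restarts` seeded restarts
(deterministic given `rng_seed`). The cluster whose centroid posture-angle
coordinate is nearer horizontal is the rest reference (RR). Points
assigned to RR (nearest-centroid, ties toward RR) score 0; other points
score the Euclidean distance to the RR centroid in the normalised 4-D
space. If all points coincide the patient's data form a single degenerate
cluster; this is surfaced as an error, not silently scored.

Window distances are summed per 15-minute interval; an interval with
n < 13 points is rescaled by 13/n so interval sums stay comparable. The
rest quality of a day's rest period is the mean over its scored
intervals. Lower is better.

Min–max normalisation makes the metric invariant to positive affine
rescaling of any raw feature column. Note that a global rescaling of the
raw accelerations is *not* an affine map of the circular-deviation
feature (|c·m − 1| ≠ c·|m − 1| when magnitudes straddle 1), so the
pipeline is exactly scale-invariant in the other three features but only
approximately in that one; the property tests assert the affine
invariance that actually holds.

## Daily scores and ingestion metrics

Per patient, three per-day series — rest quality, rest start time
(minutes from the day-window boundary, avoiding midnight wrap), and
duration — are standardised to z-scores using the patient's own mean and
**sample** SD (`sd_ddof_score=1`; constant series map to all-zero with a
warning, fewer than 2 days yield none). The composite rest score is
|z_quality| + |z_start| + |z_duration|, reported only when all three
exist.

The ingestion rate is (# distinct days with a recorded dose) / (days from
the first patch-data day through the last ingestion day, inclusive). The
daily ingestion clock time (minutes from midnight — dosing is a daytime
event) is standardised the same way.

Outlier coincidence matching pairs rest-outlier days with ingestion-time
outlier days at most `outlier_lag_days` (default 1) apart. An ingestion
outlier is |z| > 2. For the rest side, the composite score is itself a
sum of three folded z-scores with typical value ≈ 2.4, so a raw
`composite > 2` rule would flag roughly half of all days; instead the
composite series is standardised within the patient and a one-sided z > 2
flags a day (`composite_outlier_mode="zscore"`; the raw-threshold variant
is retained as `"threshold"`). "Single-day" outliers additionally require
both calendar neighbours to be non-outliers (`single_day_outliers`
toggles this).

## Synthetic generator

`simulate_patient` emulates the patch channels with planted ground truth:

* One nightly rest block: onset 23:00 ± 30 min (SD), duration 480 ± 45
  min. During rest θ ~ |5° + N(0, 8°)|, (a_y, a_z) uniform on the unit
  circle plus N(0, 0.05 g) per axis, a_x ~ N(0, 0.05 g), steps 0. Active
  minutes: θ ~ N(80°, 8°), a_x ~ N(0.95, 0.15) g, steps ~ Poisson(8).
* Awakenings: Poisson(1)/night contiguous active blocks inside the rest
  span, duration geometric with mean 3 min truncated to 1–20 min —
  nocturnal awakening durations are heavily right-skewed, and blocks of
  ≥ 5 min are what flip a 15-minute interval to ACTIVE, exercising the
  single-active-gap rescue rule.
* Missing spans (10%/day chance, 30–90 min) blank both channels; a daily
  5-minute daytime pairing span exercises the pairing criterion.
* One dose per adherent day (default probability 0.9) at 09:00 ± 30 min;
  an explicit `dose_days` list overrides the Bernoulli draw for planted
  adherence-rate experiments.
* Planted anomalies: `restless_days` amplify movement noise (×6) and
  posture jitter (×2.5) with more awakenings while keeping the night
  REST-classified; `rest_disrupt_days` delay onset by 240 min and cut
  duration by 240 min; `dose_outlier_days` shift the dose by 4 dose-time
  SDs. Planted shifts are exact (the per-day jitter is suppressed on the
  planted quantity) so recovery experiments measure detection rather than
  the generator's own night-to-night noise — standard practice for
  planted-anomaly validation. With several planted outliers the
  patient-level SDs are inflated by the plants themselves (masking), which
  is why recovered z-scores saturate near √(n_days/n_planted).

Cohorts split a master `SeedSequence` so any patient is regenerable in
isolation; the same (config, seed) pair reproduces byte-identical CSVs.

The generator emulates the *structure* of patch data, not its physiology:
no sleep architecture (stages, REM cycles), no sensor drift or
miscalibration, no posture changes within rest (side switching), no
heart-rate dynamics, and activity is a single homogeneous regime. Passing
recovery tests therefore show that the algorithm recovers what the data
model plants under realistic noise, cadence, and missingness — not that
it measures sleep in the polysomnographic sense.

## Problem sizes and numerical choices

The test suite and acceptance script use: 10 patients × 10 nights for
rest-block recovery (Jaccard vs planted truth), 100 single-patient
replicates of 8 nights (4 quiet / 4 restless) for the quality ordering,
60-day streams for adherence and outlier-coincidence experiments, and
exhaustive enumeration up to length 12 for the rest-period rules. Each
experiment derives child seeds from one master seed; k-means uses 10
restarts. Floating-point comparisons use 1e-9 tolerances; CSV floats are
written with 12 significant digits so round-trips are exact to well below
that.

## Known limitations

* The rest-period extension is a reconstruction from prose rules; the
  two-active gap case and the meaning of "within 5 intervals" (gap length
  vs candidate offset — implemented as gap length ≤ 5) are genuinely
  ambiguous and are config-exposed rather than hidden.
* Only one rest period per day is produced; naps are out of scope.
* Quality values are relative to each patient's own range and cluster
  geometry; they are not comparable across patients.
* Days without an LRP or with no scorable windows silently drop out of
  z-scoring; with < 2 surviving days a patient has no scores at all.
* The composite-outlier threshold and the SD denominators are
  conventions, exposed in `RunConfig`, not empirically validated values.
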