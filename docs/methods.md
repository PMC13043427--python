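# Methods

`mobrec` implements a smartphone digital-phenotyping pipeline for
post-operative recovery monitoring: raw duty-cycled GPS and accelerometer
traces are reduced to five daily mobility variables, cleaned and multiply
imputed into an analytic patient-day table, and analyzed with week
comparisons, GLM recovery trajectories and PROM correlations.  A calibrated
synthetic cohort generator supplies raw traces with known ground truth, so
the whole chain can be validated end to end.

## Daily mobility features

Sensors are duty-cycled: GPS records 1 min of fixes every 5 min (1 Hz within
the on-window, configurable), the accelerometer 10 s every 10 s.  All
geometry is haversine on the WGS84 mean radius (6371.0088 km); coordinates
are only projected locally (equirectangular, meters) for clustering and
segmentation decisions, where the error at city scale is far below GPS noise.

**Pauses.** A pause is a maximal contiguous run of points that stays within
`pause_radius_m` (50 m) of the run's running centroid, kept when it spans at
least `min_pause_s` (300 s).  Runs also break at observation gaps longer than
`max_gap_s` (1800 s): device silence is not taken as evidence of staying put,
although ordinary duty-cycle gaps (240 s) are bridged.

**Flights and distance.** Between pauses, the trace is decimated to vertices
spaced at least `min_vertex_m` (15 m) apart and split wherever the heading
between consecutive vertex displacements turns by more than
`heading_change_deg` (30°); each sub-segment is one flight and its length is
the chord between its first and last point.  Daily distance is the sum of
flight lengths in km.  The vertex decimation exists because at 1 Hz a
walking-pace displacement (~1.4 m) is smaller than typical GPS noise (~3 m),
so per-sample headings are noise; evaluating the turn rule at a 15 m spatial
scale keeps it meaningful.  Chord-based distance under-measures curved paths
whose per-vertex turns stay below the threshold; the generator therefore
moves in straight legs with corners at stops.

**Significant locations.** Pauses of at least 15 min across the whole
follow-up are clustered per patient with duration-weighted k-means
(k-means++, 10 restarts, fixed seed), choosing the smallest k whose maximum
within-cluster point-to-center distance is below half the 50 m separation;
centers closer than 50 m are then merged, so surviving locations are
pairwise at least 50 m apart and two pause groups separated by slightly more
than 50 m resolve into distinct locations.  **Home** is the location with
the most pause time inside the nightly 20:00–08:00 local windows (ties:
larger all-day pause time, then smaller id).  **Home duration** is the day's
pause time within 50 m of home, capped at 24 h.  A day's **count** is the
number of significant locations with any pause time that day; no minimum
dwell is required beyond pause eligibility.

**Entropy.** Daily significant-location entropy is −Σ pᵢ ln pᵢ (natural log)
over the day's non-zero occupancy shares.  The day-fraction profile
(denominator 86 400 s) is available, but the daily entropy uses shares
renormalized over the day's significant-location time.  With day fractions,
a patient at home 14.6 h/day and nowhere else would score
−0.61·ln 0.61 ≈ 0.30 nats, so entropy near 0.1 nats alongside ~15 h of home
time — the regime this pipeline is calibrated for — is only attainable with
normalized shares, which is also the convention of smartphone-mobility
feature sets.  A single-location day has entropy 0.

**Steps.** Acceleration magnitude (orientation-invariant) is band-passed to
the gait band (0.5–3 Hz, 2nd-order Butterworth, forward–backward) and peaks
above 0.1 g separated by at least 0.3 s are counted per burst and summed over
the day.  With the 50% accelerometer duty cycle the raw daily sum counts
about half the true steps; `extrapolate=True` rescales by the duty factor.
The default is the raw sum, matching the low daily step magnitudes
(~100–250) this pipeline is calibrated against.  A day with no bursts has
missing steps (not zero).

Days whose GPS on-window coverage falls below 10% have missing GPS features.

## Cleaning ladder

1. Censor at 70 post-operative days (day 70 inclusive).
2. Reindex to the complete patient × day grid; absent days become missing.
3. Per patient × variable, exclude the variable when strictly more than 50%
   of its values are missing (excluded cells are never imputed and stay out
   of analysis).
4. MICE with random-forest conditional models: each mobility variable is
   iteratively regressed on the others plus post-operative day, approach and
   patient indicators; m = 5 completed datasets, at most 50 chained sweeps
   with tolerance-based early stopping, fixed seed.  Missing rows are
   initialized from complete donor rows of nearby post-operative days
   (mean-style starts sit off the joint data manifold and make the strongly
   coupled count/entropy pair collapse onto one branch), and integer
   variables are stochastically rounded inside and after the chain
   (deterministic rounding of conditional means is biased toward the modal
   integer).  Home hours are clipped to [0, 24].
5. Consolidate by cell-wise mean (rounded mean for integer variables).
   Rubin's rules do not apply because the datasets, not estimates, are
   pooled.
6. Remove gross univariate outliers with Tukey fences at k = 3 (cell set
   missing-for-analysis, row retained; columns with zero IQR untouched) —
   an automated, testable surrogate for graphical inspection.
7. Add ln(x+1) columns for the right-skewed variables (distance, steps,
   entropy); raw columns are kept for raw-scale summaries.

Observed cells are bit-identical before and after the ladder, and the ladder
is idempotent.

## Analyses

*Week comparison.* Post-operative weeks are days 7(w−1)+1…7w (weeks 1 and 5:
days 1–7 and 29–35).  Raw-scale means with t-based 95% CIs; two-sided
Wilcoxon rank-sum (exact for small samples) on the pooled patient-day
values — the rank test is invariant to the log transform, so raw values are
used.  Observations are treated as independent across days within patients,
matching the pooled design of the tests; no mixed-model correction is
applied (a deliberate simplification, not best practice).

*Recovery GLMs.* mean(y) = g⁻¹(β₀ + β₁·day + β₂·approach +
β₃·day·approach), anterior coded 1.  Families: Gamma log-link for distance,
home duration and entropy (log link keeps the linear predictor
interpretation uniform; admissible zeros are shifted by ε = 0.01, logged);
Poisson log-link for count and steps; Gaussian as the unifying baseline.
Wald tests and CIs; α = 0.05.

*PROM correlations.* Daily VAS pairs with same-day mobility; weekly mJOA,
ODI and NDI pair with the patient's mean mobility over the 7 days ending on
the response date.  Pearson r on all available non-missing pairs with
two-sided t-test p-values, Benjamini–Hochberg adjustment across the 20 tests
(pairs with < 3 observations are not estimable and skip adjustment).  Per
pair, a Gaussian GLM of score on mobility with a pointwise 95% Wald band is
exported for visual presentation.

## Synthetic cohort

Thirteen patients (6 anterior approach, mean age 50; 7 posterior, mean age
67; 3 F / 10 M), 70-day follow-up, Europe/Rome timezone, staggered surgery
dates.  Per-arm trajectories are (intercept, slope) on the link scale — log
for distance, steps, count and entropy, identity for home hours — solved in
closed form so the pooled week-1/week-5 ground-truth means equal the
calibration targets: 3.04 → 13.89 km, 14.63 → 14.05 h home, 1.33 → 2.44
locations, 0.10 → 0.26 nats, and raw-counted steps 108.83 → 250.  Arm
contrasts encode higher anterior starting points and steeper anterior
recovery for steps and count, a declining anterior home duration against a
near-flat posterior one, and arm-neutral distance.  Growth stops at a
plateau (day 45); recovery does not extrapolate exponentially to day 70.

Each day is an explicit schedule: nights at home (the evening home block
always covers 20:00–24:00, anchoring home detection), 0–4 visits to fixed
significant places (0.5–4 km from home, each ≥ 21 min so it qualifies), and
"ambient errands" filling the remaining away time without ever minting a
significant location: chains of short outdoor dwells (~2–10 min, hopping
60 m–1.2 km between spots) interleaved with *indoor stops* — errands of
40+ minutes during which the phone has no GPS fix apart from brief
"doorstep" shoulders.  Indoor stops consume away time at zero distance
(their silent middle exceeds the pause-bridging gap, so they form no pause
at all), which is what makes a day with only ~15 h at home but just 3 km of
travel schedulable.  Transits are straight legs at 8 m/s with corners at
stops; planned distance shortfalls become shallow zig-zag detours.
Brisk-walk bouts at the start and end of the excursion carry the step
oscillation (cadence 1.8 Hz, 0.28 g on the gravity axis); ambient errands
deliberately produce no step signal, reflecting that daily step counts of
~100–250 cannot be coherent with km-scale travel.  Ground truth records the
exact haversine path length, stay occupancies and their entropy, and
steps = cadence × walking seconds.

Counts are integerized by per-patient error diffusion (a carry
accumulator over the fractional daily rate, random initial phase) rather
than a Poisson draw: people space errands out quasi-regularly, and the
tight printed CI for the count variable (±0.07 at n = 91) implies a daily
dispersion far below Poisson.  Visit durations are solved per day
by bisection against a Monte-Carlo expectation of realized entropy that
mirrors the generator's own noise pipeline, so entropy is induced through
the occupancy schedule rather than drawn directly.  Home-hours noise is set
small enough that the week-1 vs week-5 rank test reaches p < 0.001 as in
the calibration targets; the printed home CI half-width (±1.0 h) would
imply a daily dispersion under which that p-value is unreachable for a
0.58 h shift, so the generator reproduces the inferential outcomes and the
means rather than the (mutually inconsistent) dispersions.

Two structural facts shape the generator.  First, *outdoor*
away-from-home time that is not at a significant place must keep drifting —
any stationary outdoor quarter hour would create a qualifying pause and
pollute the location set — so stationary away time lives in the GPS-silent
indoor stops and outdoor dwells stay well under 15 min.  Second, ambient
relocations are scheduled inside GPS off-windows (`align_hops_to_gaps`, on
by default): chord-based flights lose the observed entry/exit meters of
every short hop — roughly 25 m per hop, up to 15% of a day's distance —
which is an artifact of duty-cycled chord measurement, not of the
estimators under test.  Alignment targets the nominal schedule grid so stay
durations stay unbiased.  Without alignment the pipeline still recovers
distance with regression slope ≈ 0.95 but a −15% level bias.

Day-level MCAR missingness (default 10%) empties whole sensor days,
matching the daily granularity at which the cleaning ladder operates.
Daily VAS and weekly mJOA/ODI/NDI are linear in the (standardized) true
anchor mobility variable — VAS and ODI/NDI anchor to distance, mJOA to
steps — with Gaussian noise solving b/√(b²+σ²) = target r (VAS −0.358,
mJOA 0.403, ODI −0.409, NDI −0.279); scores are rounded and clipped to
native scales afterwards (truncation effects are second order).  Response
rates (VAS 52%, weekly ~70%) reproduce the study-scale survey counts
(~460 daily, ~90 weekly).

What the generator does **not** emulate: street networks or travel modes
(straight legs only), within-day sensor outages, multi-device artifacts,
heavy-tailed daily dispersion of distance and steps seen in real cohorts,
seasonal/weekday structure, or informative (MNAR) missingness.  Passing
tests therefore demonstrate estimator correctness under the stated
measurement model, not robustness to every property of real exports.

## Numerical choices and determinism

Everything stochastic flows from one integer seed through hierarchical
`numpy` SeedSequences (per-patient streams; a separate stream for PROMs);
repeated runs are byte-identical.  k-means uses a fixed random state and 10
restarts.  The entropy solver uses frozen internal draws.  The exact
Wilcoxon method is used when both samples are ≤ 25.  Degenerate inputs:
empty traces give empty pauses/flights; a day with no GPS yields missing
GPS features; constant responses yield flat GLM fits with zero slopes;
zero-IQR columns are never outlier-filtered.

## Problem sizes used in validation

The shipped validation runs the full 13-patient, 70-day cohort once
(~16 M GPS points, ~4 M accelerometer samples) for the end-to-end checks;
calibration properties use 20 replicates of a 35-day cohort without sensor
rendering; GLM coverage uses 200 replicates at 910 patient-days.
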