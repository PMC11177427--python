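# Methods

This note documents the models and procedures implemented in
`tripfidelity`, the defaults and why they were chosen, what the synthetic
colony generator does and does not emulate, and the numerical decisions
made where the design was genuinely open.

## Cleaning and segmentation

Raw fix tables pass through a fixed-order pipeline: deployment-window
filter → plausibility filter → duplicate-timestamp resolution →
identical-consecutive removal → speed filter → gap segmentation. Order
matters: duplicates must be resolved before speeds can be computed (a zero
time step would make speed undefined), and the speed filter must see the
deduplicated, artefact-free track.

- **Duplicate timestamps.** Which of two fixes sharing an instant is real
  is unknowable, so one is kept uniformly at random from an explicit,
  seeded generator; the choice is reproducible and each duplicate is
  equally likely.
- **Identical-consecutive fixes.** Some archival tags emit runs of fixes
  identical in position, altitude, bearing and speed under fresh
  timestamps. Scanning left to right and comparing each fix with its
  surviving predecessor collapses a whole run to its first member. Only
  columns present in the file are compared; missing compares equal to
  missing.
- **Speed filter.** Speeds are recomputed from positions (great-circle
  distance over elapsed time) rather than trusting tag speed fields, which
  are absent for some tags. The filter is applied iteratively: the later
  fix of any consecutive pair faster than 30 m s⁻¹ is dropped and the next
  fix is re-checked against the surviving predecessor, so the output
  provably contains no super-threshold pair. A single pass that does not
  re-check can leave such pairs behind. 30 m s⁻¹ sits above realistic
  auk/kittiwake flight speeds (13–19 m s⁻¹) with headroom for tail winds.
- **Segmentation.** Tracks split where consecutive fixes are more than one
  hour apart (a gap of exactly one hour does not split). Trip assignment
  runs per segment so data gaps cannot fabricate colony departures.
- The plausibility region defaults to a 500 km radius around the colony —
  an order of magnitude beyond these species' foraging ranges — and is
  configurable; with no colony supplied the filter is skipped and noted in
  the cleaning report. The report's per-rule counts always reconcile
  exactly with the input/output row delta.

Timestamps are stored at 1 s resolution in UTC; offset-bearing inputs are
converted on read. Sub-second precision is never needed at 4 s dive
sampling and ≥ 1 min fix schedules.

## Trips

A trip is a maximal run of fixes more than the buffer radius (default
500 m) from the bird's **own capture area** — not an island centroid —
whose first-to-last away-fix span is at least 30 min; shorter excursions
are treated as bathing/preening. The span rule (rather than cumulative
away time) is simpler and robust to within-trip gaps. The adjacent
at-colony fix on each side is included when present; a trip is *complete*
iff both exist. Trip start/end instants are those bounding fixes'
timestamps when present, which matches the buffer's semantics (the bird
was last/first seen at the colony then).

The distal fix maximises great-circle distance from the capture area, ties
broken by the earlier fix; the trip bearing is the spherical initial
azimuth from capture area to distal fix, in (−π, π]. All geometry is
spherical (haversine, R = 6371.0088 km); ellipsoidal geodesics differ by
well under 0.5% at these ranges, which is far below the behavioural signal.

## Resampling

Before metric computation every trip is subsampled to a 10-minute interval
with ±60 s tolerance by a greedy forward scan: keep the first fix, then the
earliest fix whose gap from the last kept fix falls in [540 s, 660 s];
fixes closer than 540 s are skipped; a gap beyond 660 s keeps the next
available fix and restarts the clock. Two invariants pin the dialect:
output gaps are never below 540 s, and resampling is idempotent. Distal
fix and bearing are recomputed on the subsampled trip (`distal_on_resampled`
behaviour), because the metrics are defined on the resampled data and the
original distal fix may have been dropped; trip start/end (and hence
durations) keep the full-resolution values.

## Fidelity metrics

The NND uses the pooled-mean form — the sum of nearest-neighbour distances
in both directions divided by the total fix count — which is symmetric,
keeps km units interpretable, and is insensitive to which trip is called
focal. The alternative sum-of-two-directional-means is available via
`nnd(..., form="sum_of_means")`. Distal distance is geodesic
(great-circle), and bearing differences wrap to [0, π]; an unwrapped
absolute difference can exceed π, which is geometrically meaningless for
direction similarity. Bearings are stored in radians; reported tables
convert to degrees.

## Comparison designs

The fidelity test contrasts an empirical distribution (same-bird pairs)
with a null (different-bird pairs) at **equal counts per focal unit**, so
individuals with more trips carry proportionally more weight:

- *Within-year*: all unordered same-bird same-year pairs (birds with ≥ 2
  complete trips); for each, one comparison trip drawn from other
  conspecifics tracked that year, uniformly over (bird, trip) pairs,
  without matching by date (matching would shrink the candidate pool).
- *Between-year*: all same-bird cross-year pairs per year pair; the
  between sample pairs the focal bird's earlier-year trips with trips of
  other conspecifics tracked in the later year. Records carry the year
  separation and the difference in trip timing relative to each year's
  median laying date; records missing a laying date are flagged and fall
  out of models using that covariate.
- *Same-day*: one sampled trip per individual per species × day × year
  (trips spanning midnight are eligible via their start date, so long
  trips are not excluded). Within-day pairs are compared within species
  (all pairs) and across species (one sampled comparator per focal trip,
  built over ordered species pairs so no unordered pair appears twice);
  between-day analogues use one alternative day per stratum, giving equal
  within-/between-day counts per day. The between-day comparator excludes
  the focal individual — otherwise individual route fidelity leaks into
  the day contrast (a logged self-comparison fallback exists for the
  degenerate case where the alternative day holds only the focal bird).

Sampling is without replacement when the pool suffices, with replacement
otherwise (logged per stratum). Day boundaries are UTC midnight. A fixed
seed reproduces a comparison table exactly; different seeds change only the
sampled (between/alternative-day) rows.

## Dive bouts and effort

Dive records less than 300 s apart join one bout (exactly 300 s splits);
bout duration runs first record to last, with no padding for the 4 s
sampling cadence (≤ 4 s truncation). A bout belongs to a trip iff its
start lies inside the trip; bouts are not split across trips (dives
require being at sea, so boundary cases are degenerate), but bout time past
the trip end is clipped out of the total/proportion metrics
(`clip=False` disables). Trips without bouts carry missing effort values
rather than zeros — absence of dive data is not evidence of zero foraging.

## Temporal overlap

"At the colony" reuses the 500 m trip-splitting buffer — one spatial
convention throughout. Colony overlap is the closed-interval intersection
of two birds' pre-departure presence intervals (single fix suffices;
touching endpoints count, negligible at 1 s resolution) and is deliberately
binary. At-sea overlap is shared time over summed durations, bounded by
0.5 (attained exactly for identical intervals); zero-overlap pairs are
excluded from the overlap models because such trips can be minutes or many
hours apart and are uninformative about shared conditions.

## Mixed models

All three metrics are non-negative and right-skewed; they are √-transformed
before fitting (legal since the metrics are ≥ 0 by construction) and
numeric covariates are z-scored so effect sizes are comparable. Random
intercept structures follow the design: individual nested in tracking year
(within-year fidelity), individual (between-year and effort), year
(same-day), day nested in year (overlap models). A grouping factor with a
single level is dropped automatically (e.g. individual-in-year collapses
to individual in a one-year dataset) — a one-group mixed fit is
numerically ill-posed.

Numerical and inferential choices:

- REML for estimate tables; ML refits for likelihood-ratio tests of a
  random-effect variance, with the statistic floored at zero (boundary
  estimates can make it marginally negative) and referred to χ²₁ without
  the 50:50 boundary mixture correction — the plain χ²(1) reference is
  the conservative, conventional report.
- Fixed-effect tests use Wald **t** statistics with between-within
  (containment) degrees of freedom: df = n − m − p for effects varying
  within the finest random factor (m levels, p fixed parameters). The
  asymptotic z reference is anticonservative at realistic individual
  counts: with 20 birds it inflated the null rejection rate of the
  fidelity contrast to ≈ 6.8%; the containment t brings it to ≈ 4%
  (measured over 600 null simulations). Satterthwaite approximation would
  be preferable but is not available from the fitting backend's outputs.
- Marginal means per comparison type are evaluated at covariate means
  (zero after centring) on the √ scale and squared back to natural units,
  CIs by squaring the √-scale interval endpoints. Squaring the endpoints
  (rather than a delta-method variance) keeps the interval inside the
  response's support; for the effect sizes involved the two differ little.
- The capture-area distance covariate enters only the NND and
  distal-distance models (bearing does not depend on where a trip starts)
  and is dropped automatically when it has zero variance — e.g. a species
  caught at a single capture area.
- Variance inflation factors are available (`vif`) for covariate-set
  diagnostics; perfectly collinear columns report infinity.
- Non-convergence falls back to an OLS fit with `converged=False`;
  near-zero variance components set a `singular` flag rather than raising.

## The synthetic colony generator

`simulate_population` emulates the structure the analysis must detect, not
seabird movement per se:

- Each bird has a preferred direction ~ von Mises(colony mean, κ_pop) and a
  preferred distal distance ~ log-normal; each trip draws a direction
  ~ von Mises(preference, κ_ind) and a jittered distance. κ_ind large
  relative to the between-bird spread ⇒ within-individual trips are more
  similar than between — fidelity. Setting κ_ind = κ_pop = 0 with zero
  between-bird distance spread makes all trips iid across birds: the
  no-fidelity null used for calibration (with a hierarchical preference
  model, equal concentrations alone do not give exchangeability; the null
  is the absence of the individual-level component).
- Per-trip random drift of each bird's preference (wrapped-normal steps,
  default 0.03 rad) erodes fidelity with time between trips, and a
  per-day shared direction blended with weight `social_weight` couples
  same-day trips — together these reproduce the qualitative decay of
  fidelity with time separation and the negative at-sea-overlap slope on
  NND.
- Trips are out-and-back commutes at species cruising speed (defaults from
  published flight speeds: guillemot 19.1, razorbill 16.0, puffin 17.6,
  kittiwake 13.1 m s⁻¹) with a loitering phase at the target (small-step
  random walk; uniform per-trip duration jitter) where dive bouts are
  planted: per-trip count uniform on 1..3, log-normal durations (median
  4 min), 4 s record cadence, 10 min between bouts. `vary_bouts=False`
  plants exact fixed bouts for recovery tests. Colony attendance intervals
  separate trips; fixes are emitted on the tag schedule with 25 m Gaussian
  noise. Default distal distances (log-mean 25 km) and 1–3 tracked days
  with 1–2 trips/day mirror a realistic auk colony study's scale.
- The truth record stores each trip's latent target *and* the realized
  distal point of the noise-free track; recovery checks compare against
  the realized point, which is what a distal-fix detector can in principle
  find (the loiter walk legitimately moves the bird off its latent target).

Not emulated: environmental fields and prey dynamics, area-restricted
search, flight mechanics, wind, tag failure, or behaviour-dependent fix
loss. Passing tests therefore demonstrate that the pipeline recovers
planted structure of this kind at realistic sampling scales — not that
real seabird data satisfy the generator's assumptions.

## Test problem sizes

The simulation-backed checks use deliberately modest scales: trip recovery
on 20 birds × 5 trips; bout recovery on 100 birds; detection power over 50
replicates of an 8-bird, 32-trip colony with strong preferences (κ_ind = 8,
κ_pop = 0.7); null calibration over 200 replicates of a 20-bird iid-trip
colony; CI coverage over 200 tables drawn directly from the fitted model
family. These sizes give stable Monte-Carlo behaviour for the properties
asserted while keeping the full suite fast.

## Known limitations

- Between-within df is an approximation; Satterthwaite/Kenward-Roger would
  be preferable for small, unbalanced designs.
- Comparison records share trips, so records are not fully independent
  beyond what the random intercepts capture; this mirrors the analysis
  design the pipeline implements, and the calibration check bounds its
  practical effect at the simulated scales.
- Spherical geometry throughout; at ranges ≫ 1000 km an ellipsoidal
  backend would be warranted.
- The same-day design draws one alternative day per stratum rather than
  integrating over all other days; estimates are unbiased but slightly
  noisier than a full enumeration.
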