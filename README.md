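# tripfidelity

Foraging-site and route-fidelity analysis for central-place foragers.

Colonial seabirds (guillemots, puffins, razorbills, kittiwakes, …) commute
from a fixed breeding site to foraging grounds at sea. Whether an
individual repeats the same route or foraging site — and what erodes that
fidelity — matters for predicting how populations respond to environmental
change. `tripfidelity` turns raw GPS fix tables and time-depth-recorder
(TDR) dive logs into that analysis end to end:

1. **Cleaning** — deployment-window and plausibility filters, seeded
   resolution of duplicate timestamps, removal of identical-consecutive tag
   artefacts, an iterative 30 m s⁻¹ speed filter, and segmentation at
   track gaps of more than one hour.
2. **Trip assignment** — a foraging trip is a maximal run of fixes more
   than 500 m from the bird's own capture area lasting at least 30 min;
   only *complete* trips (observed leaving and returning) are analysed.
3. **Resampling** — trips are subsampled to a common 10-minute fix
   interval (±60 s tolerance) so tag schedules cannot bias the metrics.
4. **Fidelity metrics** — for a trip pair (A, B):
   - route similarity, the bidirectional mean nearest-neighbour distance

     `NND = ( Σ_{a∈A} min_b d(a,b) + Σ_{b∈B} min_a d(a,b) ) / (n_A + n_B)`;
   - foraging-site similarity, the great-circle distance between the two
     *distal* fixes (each trip's farthest point from the capture area);
   - directional similarity, the minimal circular difference of trip
     bearings, `min(|θ_A−θ_B|, 2π−|θ_A−θ_B|) ∈ [0, π]`.
5. **Comparison designs** — balanced within-individual (empirical) versus
   between-individual (null) trip pairs, within one year, across years, and
   on the same versus different days; equal counts per focal unit.
6. **Dive bouts and effort** — TDR records under 5 min apart form one
   foraging bout; per-trip effort = time to first bout, mean bout duration,
   total foraging time, proportion of trip spent foraging.
7. **Temporal overlap** — pre-departure colony co-presence (yes/no) and
   at-sea overlap, `shared time / (dur_A + dur_B) ∈ [0, 0.5]`.
8. **Mixed models** — Gaussian LMMs on √-transformed metrics with
   standardized covariates and random intercepts (individual, individual
   within year, or day within year); Wald *t* tests with between-within
   degrees of freedom, marginal means squared back to natural units, and
   likelihood-ratio tests of the individual variance (ML, χ²₁).

A synthetic colony generator (`simulate_population`) produces GPS and TDR
data with known individual preferences (von Mises directions, log-normal
distal distances), day-level social coupling, and planted dive bouts, so
every stage can be validated against ground truth.

## Worked example

`examples/03_within_year_fidelity.py` simulates a colony of 12 guillemots
with strong individual direction preferences, runs the full pipeline, and
fits the within-year fidelity model:

```
                    nnd_km  distal_km
comparison_type
between_individual   15.64      31.46
within_individual     7.31      10.72

NND within-individual:  7.19 km (5.92-8.60)
NND between-individual: 13.82 km (12.02-15.74)
contrast p = 1.2e-19
individual variance LRT: chi2(1) = 46.01, p = 1.2e-11
```

Trips by the same bird are about half as far apart (7.2 km mean
nearest-neighbour distance) as trips by different birds (13.8 km): route
fidelity. The likelihood-ratio test says birds differ significantly in how
faithful they are. The other scripts in `examples/` each demonstrate one
capability (cleaning/trip splitting, the metrics, dive-bout effort,
temporal overlap).

Typical use from Python:

```python
import numpy as np
import tripfidelity as tf

gps = tf.read_gps("gps.csv")
site = tf.SiteRegistry.from_yaml("sites.yaml")
clean, report = tf.clean_gps(gps, np.random.default_rng(1), colony=site.capture_areas["A"])
trips = [tf.resample_trip(t, site) for t in tf.filter_complete(tf.assign_trips(clean, site))]
table = tf.within_year_design(trips, site, np.random.default_rng(2))
result = tf.run_analysis("within_year", table)
```

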