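"""Detect foraging bouts from dive records and relate effort to fidelity.

Dive (TDR) records under five minutes apart form one foraging bout. The
four per-trip effort metrics (time to first bout, mean bout duration, total
foraging time, proportion of trip spent foraging) become covariates in a
model of fidelity between consecutive trips.
"""
import numpy as np

import tripfidelity as tf

cfg = tf.SimConfig(
    species=[tf.SpeciesConfig("razorbill", n_birds=10, n_days=3, trips_per_day=2,
                              years=(2020, 2021))]
)
gps, tdr, site, _ = tf.simulate_population(cfg, seed=8)
clean, _ = tf.clean_gps(gps, np.random.default_rng(9), colony=(cfg.colony_lat, cfg.colony_lon))
trips = [tf.resample_trip(t, site) for t in tf.filter_complete(tf.assign_trips(clean, site))]

bouts = tf.detect_bouts(tdr)
print(f"{len(bouts)} foraging bouts; mean duration {bouts.duration_min.mean():.1f} min")

consec = tf.consecutive_trip_table(trips, bouts, site)
print(consec[["nnd_km", "time_to_first_bout_min", "total_foraging_min", "prop_foraging"]]
      .describe().loc[["mean", "std"]].round(2))

fit = tf.run_analysis("effort", consec, responses=("nnd",), with_lrt=False)["fits"][("nnd", "base")]
print("\neffort model coefficients (sqrt-km per SD of covariate):")
print(fit.summary_frame().round(3))
# Negative coefficients mean trips following that kind of foraging
# experience were *more* similar to the next trip (stronger fidelity).
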