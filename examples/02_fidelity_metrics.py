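"""Compute the three pairwise fidelity metrics for two trips.

Builds two trips of one bird heading in nearly the same direction, resamples
both to the common 10-minute schedule, and prints the route similarity
(NND), foraging-site similarity (distal distance), and direction similarity
(bearing difference).
"""
import math

import tripfidelity as tf

cfg = tf.SimConfig(
    species=[tf.SpeciesConfig("razorbill", n_birds=1, n_days=2, trips_per_day=1,
                              kappa_ind=25.0)]
)
import numpy as np

gps, _, site, _ = tf.simulate_population(cfg, seed=3)
clean, _ = tf.clean_gps(gps, np.random.default_rng(0), colony=(cfg.colony_lat, cfg.colony_lon))
t1, t2 = tf.filter_complete(tf.assign_trips(clean, site))[:2]
t1 = tf.resample_trip(t1, site)
t2 = tf.resample_trip(t2, site)

triple = tf.fidelity_triple(t1, t2, site)
print(f"NND:                {triple.nnd_km:.2f} km   (mean fix-to-nearest-fix distance, both directions)")
print(f"distal distance:    {triple.distal_km:.2f} km   (between the two farthest points)")
print(f"bearing difference: {math.degrees(triple.bearing_diff_rad):.1f} deg  (direction of travel)")
print(f"time between starts: {triple.dstart_min:.0f} min")
# Small values on all three metrics mean the bird repeated its route,
# its foraging site, and its departure direction.
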