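"""Clean a raw GPS table and split it into foraging trips.

Simulates a small tracked colony, writes the raw fixes to CSV, reads them
back through the standard reader, applies the cleaning rules, and assigns
foraging trips against the 500 m colony buffer.
"""
import numpy as np

import tripfidelity as tf

cfg = tf.SimConfig(
    species=[tf.SpeciesConfig("guillemot", n_birds=5, n_days=2, trips_per_day=2)]
)
gps, tdr, site, truth = tf.simulate_population(cfg, seed=1)

tf.write_table(gps, "scratch_gps.csv")
gps = tf.read_gps("scratch_gps.csv")

clean, report = tf.clean_gps(
    gps, np.random.default_rng(2), colony=(cfg.colony_lat, cfg.colony_lon)
)
print("cleaning report:", report.as_dict())

trips = tf.assign_trips(clean, site)
complete = tf.filter_complete(trips)
print(f"planted trips: {len(truth['trips'])}, recovered complete trips: {len(complete)}")
summary = tf.trips_to_frame(complete)
print(summary[["trip_id", "duration_h", "distal_distance_km", "bearing_rad"]].head())
# Each row is one colony-to-colony foraging trip; distal_distance_km is how
# far the bird went, bearing_rad the direction of its farthest point.
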