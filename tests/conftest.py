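import numpy as np
import pandas as pd
import pytest

from tripfidelity import SiteRegistry, fit_lmm, within_year_design
from tripfidelity.geo import destination_point
from tripfidelity.trips import Trip, trip_summary

COLONY = (56.185, -2.557)


@pytest.fixture
def site():
    lat_b, lon_b = destination_point(COLONY[0], COLONY[1], np.pi / 4, 0.3)
    return SiteRegistry(
        capture_areas={"A": COLONY, "B": (float(lat_b), float(lon_b))},
        buffer_radius_m=500.0,
    )


def make_fixes(bird, times_s, lats, lons, species="guillemot", year=2021, area="A", **extra):
    """Fix table from second offsets (from an arbitrary epoch) and positions."""
    t0 = pd.Timestamp("2021-06-01 06:00:00", tz="UTC")
    df = pd.DataFrame(
        {
            "bird_id": bird,
            "species": species,
            "year": year,
            "capture_area": area,
            "timestamp": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


def make_trip(
    site,
    trip_id,
    bird,
    bearing_rad,
    dist_km,
    start="2021-06-01 06:00:00",
    species="guillemot",
    year=2021,
    area="A",
    duration_h=4.0,
    n_leg=4,
):
    """Synthetic out-and-back trip along one bearing, summarised."""
    lat0, lon0 = site.location(area)
    start = pd.Timestamp(start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    end = start + pd.Timedelta(hours=duration_h)
    dists = list(np.linspace(0, dist_km, n_leg + 1)) + list(
        np.linspace(dist_km, 0, n_leg + 1)[1:]
    )
    lats, lons = [], []
    for d in dists:
        la, lo = destination_point(lat0, lon0, bearing_rad, d)
        lats.append(float(la))
        lons.append(float(lo))
    times = pd.date_range(start, end, periods=len(dists))
    fixes = pd.DataFrame(
        {
            "bird_id": bird,
            "species": species,
            "year": year,
            "capture_area": area,
            "timestamp": times,
            "lat": lats,
            "lon": lons,
        }
    )
    trip = Trip(
        trip_id=trip_id, bird_id=bird, species=species, year=year,
        capture_area=area, fixes=fixes, complete=True, start=start, end=end,
    )
    return trip_summary(trip, site)


def run_within_year_contrast(cfg, seed, responses=("nnd", "distal", "bearing")):
    """Full pipeline on one simulated colony; Wald test of the
    within/between-individual contrast per response."""
    import tripfidelity as tf

    gps, _, sim_site, _ = tf.simulate_population(cfg, seed)
    rng = np.random.default_rng(seed + 1_000_003)
    clean, _ = tf.clean_gps(gps, rng, colony=(cfg.colony_lat, cfg.colony_lon))
    trips = tf.filter_complete(tf.assign_trips(clean, sim_site))
    resampled = [tf.resample_trip(t, sim_site) for t in trips]
    table = within_year_design(resampled, sim_site, rng)
    out = {}
    for resp in responses:
        fixed = ["comparison_type", "dstart_min"]
        if resp in ("nnd", "distal"):
            fixed.append("capture_dist_m")
        fit = fit_lmm(table, resp, fixed, random="individual_in_year")
        coef = float(fit.params["comparison_type_between_individual"])
        p = float(fit.pvalues["comparison_type_between_individual"])
        out[resp] = (coef, p)
    return out
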