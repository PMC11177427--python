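"""Pairwise trip-fidelity metrics.

Three complementary metrics describe how similar two foraging trips are:

* ``nnd`` — mean nearest-neighbour distance between the trips' fixes,
  computed bidirectionally (every fix of each trip to its nearest fix on
  the other) so the result is symmetric and not biased by which trip is
  focal or by trip length. Captures whole-route similarity.
* ``distal_distance`` — great-circle distance between the two distal fixes,
  a proxy for similarity of the primary foraging site.
* ``bearing_difference`` — minimal circular difference between trip
  bearings, in [0, pi]; similarity of travel direction from the colony.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import circular_difference_rad, haversine_km, pairwise_haversine_km
from .io import SiteRegistry
from .trips import Trip


@dataclass(frozen=True)
class FidelityTriple:
    """The three fidelity metrics for one trip pair, plus pair covariates."""

    nnd_km: float
    distal_km: float
    bearing_diff_rad: float
    capture_dist_m: float
    dstart_min: float


def nnd(trip_a: Trip, trip_b: Trip, form: str = "pooled_mean") -> float:
    """Bidirectional mean nearest-neighbour distance between two trips, km.

    ``pooled_mean`` (default) sums each fix's nearest-neighbour distance in
    both directions and divides by the total number of fixes; it is
    symmetric and stays in interpretable km. ``sum_of_means`` instead adds
    the two directional means.
    """
    if len(trip_a) == 0 or len(trip_b) == 0:
        raise ValueError("nnd requires non-empty trips")
    d = pairwise_haversine_km(
        trip_a.fixes["lat"].to_numpy(),
        trip_a.fixes["lon"].to_numpy(),
        trip_b.fixes["lat"].to_numpy(),
        trip_b.fixes["lon"].to_numpy(),
    )
    a_to_b = d.min(axis=1)
    b_to_a = d.min(axis=0)
    if form == "pooled_mean":
        return float((a_to_b.sum() + b_to_a.sum()) / (len(a_to_b) + len(b_to_a)))
    if form == "sum_of_means":
        return float(a_to_b.mean() + b_to_a.mean())
    raise ValueError(f"unknown nnd form '{form}'")


def distal_distance(trip_a: Trip, trip_b: Trip) -> float:
    """Great-circle distance between the two trips' distal fixes, km."""
    return float(
        haversine_km(trip_a.distal_lat, trip_a.distal_lon, trip_b.distal_lat, trip_b.distal_lon)
    )


def bearing_difference(trip_a: Trip, trip_b: Trip) -> float:
    """Minimal circular difference between trip bearings, radians in [0, pi]."""
    return float(circular_difference_rad(trip_a.bearing_rad, trip_b.bearing_rad))


def fidelity_triple(
    trip_a: Trip, trip_b: Trip, site: SiteRegistry, nnd_form: str = "pooled_mean"
) -> FidelityTriple:
    """All three metrics plus the pair covariates for one trip pair.

    Covariates: great-circle distance between the two capture areas (m) and
    the absolute difference between trip start instants (min).
    """
    lat_a, lon_a = site.location(trip_a.capture_area)
    lat_b, lon_b = site.location(trip_b.capture_area)
    return FidelityTriple(
        nnd_km=nnd(trip_a, trip_b, form=nnd_form),
        distal_km=distal_distance(trip_a, trip_b),
        bearing_diff_rad=bearing_difference(trip_a, trip_b),
        capture_dist_m=float(haversine_km(lat_a, lon_a, lat_b, lon_b)) * 1000.0,
        dstart_min=abs((trip_a.start - trip_b.start).total_seconds()) / 60.0,
    )
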