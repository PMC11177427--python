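"""Temporal overlap between trips: co-presence at the colony and at sea.

Two birds that are at the colony together before departing, or at sea at
the same time, have the opportunity to use the same local cues or observe
one another. Colony overlap is a yes/no on the intersection of the two
birds' pre-departure colony-presence intervals (restricted to pairs from
the same capture area); at-sea overlap is the shared trip time divided by
the sum of the two trip durations, which is at most 0.5 (identical
intervals).
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .geo import haversine_km
from .io import SiteRegistry
from .metrics import fidelity_triple
from .trips import Trip


def colony_presence_interval(
    bird_fixes: pd.DataFrame,
    focal_trip: Trip,
    site: SiteRegistry,
    previous_trip_end: pd.Timestamp | None = None,
    radius_m: float | None = None,
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Interval spanned by a bird's at-colony fixes before a focal trip.

    The window opens at the end of the bird's previous trip (or at the start
    of tracking) and closes at the focal trip's start; within it, fixes
    within ``radius_m`` (default: the registry buffer) of the bird's capture
    area count as colony presence. Returns None when no such fix exists.
    """
    if radius_m is None:
        radius_m = site.buffer_radius_m
    lat0, lon0 = site.location(focal_trip.capture_area)
    window = bird_fixes[bird_fixes["timestamp"] <= focal_trip.start]
    if previous_trip_end is not None:
        window = window[window["timestamp"] >= previous_trip_end]
    if window.empty:
        return None
    at_colony = (
        haversine_km(lat0, lon0, window["lat"].to_numpy(), window["lon"].to_numpy()) * 1000.0
        <= radius_m
    )
    present = window[at_colony]
    if present.empty:
        return None
    return present["timestamp"].iloc[0], present["timestamp"].iloc[-1]


def intervals_overlap(a: tuple | None, b: tuple | None) -> bool:
    """Closed-interval intersection test; touching endpoints count."""
    if a is None or b is None:
        return False
    return a[0] <= b[1] and b[0] <= a[1]


def at_sea_overlap(trip_a: Trip, trip_b: Trip) -> float:
    """Shared trip time over the sum of the two durations, in [0, 0.5]."""
    shared = (
        min(trip_a.end, trip_b.end) - max(trip_a.start, trip_b.start)
    ).total_seconds()
    shared = max(0.0, shared)
    total = (trip_a.end - trip_a.start).total_seconds() + (
        trip_b.end - trip_b.start
    ).total_seconds()
    return shared / total if total > 0 else 0.0


def _previous_trip_end(trip: Trip, all_trips: list[Trip]) -> pd.Timestamp | None:
    prev = [t for t in all_trips if t.bird_id == trip.bird_id and t.end <= trip.start
            and t.trip_id != trip.trip_id]
    return max((t.end for t in prev), default=None)


def _sample_one_per_bird(trips: list[Trip], rng: np.random.Generator) -> list[Trip]:
    by_bird: dict[str, list[Trip]] = defaultdict(list)
    for t in sorted(trips, key=lambda t: (t.bird_id, t.start, t.trip_id)):
        by_bird[t.bird_id].append(t)
    return [by_bird[b][int(rng.integers(len(by_bird[b])))] for b in sorted(by_bird)]


def colony_overlap_table(
    trips: list[Trip],
    clean_fixes: pd.DataFrame,
    site: SiteRegistry,
    rng: np.random.Generator,
    nnd_form: str = "pooled_mean",
) -> pd.DataFrame:
    """Pairs of same-capture-area conspecific trips with colony-overlap flags.

    Per species x capture area x day, one complete trip per individual is
    sampled; every pair of those is compared, recording whether the two
    birds' pre-departure colony-presence intervals intersected, plus the
    fidelity metrics of the pair.
    """
    strata: dict[tuple, list[Trip]] = defaultdict(list)
    for t in trips:
        strata[(t.species, t.capture_area, t.year, t.start.date())].append(t)
    rows = []
    for key in sorted(strata):
        species, area, year, day = key
        chosen = _sample_one_per_bird(strata[key], rng)
        if len(chosen) < 2:
            continue
        intervals = {}
        for t in chosen:
            fixes_b = clean_fixes[clean_fixes["bird_id"] == t.bird_id]
            intervals[t.trip_id] = colony_presence_interval(
                fixes_b, t, site, previous_trip_end=_previous_trip_end(t, trips)
            )
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                ta, tb = chosen[i], chosen[j]
                triple = fidelity_triple(ta, tb, site, nnd_form=nnd_form)
                rows.append(
                    {
                        "trip_id_a": ta.trip_id,
                        "trip_id_b": tb.trip_id,
                        "bird_a": ta.bird_id,
                        "bird_b": tb.bird_id,
                        "species": species,
                        "capture_area": area,
                        "year": year,
                        "day": day,
                        "colony_overlap": intervals_overlap(
                            intervals[ta.trip_id], intervals[tb.trip_id]
                        ),
                        "nnd_km": triple.nnd_km,
                        "distal_km": triple.distal_km,
                        "bearing_diff_rad": triple.bearing_diff_rad,
                        "capture_dist_m": triple.capture_dist_m,
                        "dstart_min": triple.dstart_min,
                    }
                )
    return pd.DataFrame(rows)


def at_sea_overlap_table(
    trips: list[Trip],
    site: SiteRegistry,
    rng: np.random.Generator,
    nnd_form: str = "pooled_mean",
    drop_zero: bool = True,
) -> pd.DataFrame:
    """Pairs of same-species same-day trips with their at-sea overlap.

    One complete trip per individual per species/day (capture areas may
    differ). Pairs with zero temporal overlap are excluded by default: such
    trips may be separated by minutes or by many hours, which makes them
    uninformative about shared conditions.
    """
    strata: dict[tuple, list[Trip]] = defaultdict(list)
    for t in trips:
        strata[(t.species, t.year, t.start.date())].append(t)
    rows = []
    for key in sorted(strata):
        species, year, day = key
        chosen = _sample_one_per_bird(strata[key], rng)
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                ta, tb = chosen[i], chosen[j]
                prop = at_sea_overlap(ta, tb)
                if drop_zero and prop == 0.0:
                    continue
                triple = fidelity_triple(ta, tb, site, nnd_form=nnd_form)
                rows.append(
                    {
                        "trip_id_a": ta.trip_id,
                        "trip_id_b": tb.trip_id,
                        "bird_a": ta.bird_id,
                        "bird_b": tb.bird_id,
                        "species": species,
                        "year": year,
                        "day": day,
                        "at_sea_overlap": prop,
                        "nnd_km": triple.nnd_km,
                        "distal_km": triple.distal_km,
                        "bearing_diff_rad": triple.bearing_diff_rad,
                        "capture_dist_m": triple.capture_dist_m,
                        "dstart_min": triple.dstart_min,
                    }
                )
    return pd.DataFrame(rows)
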