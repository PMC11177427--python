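"""Foraging-trip assignment against the colony buffer, and trip summaries.

A trip is a maximal run of fixes more than the buffer radius (default
500 m) from the bird's own capture area, lasting at least 30 minutes,
extended to include the bounding at-colony fixes when present. A trip is
*complete* when both bounding fixes exist (the bird was observed leaving
and returning); only complete trips enter the fidelity analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import haversine_km, initial_bearing_rad
from .io import SiteRegistry

MIN_TRIP_DURATION_S = 30 * 60.0


@dataclass(eq=False)
class Trip:
    """One foraging trip: an ordered fix sequence plus derived summaries.

    ``bearing_rad`` is the initial geodesic azimuth from the capture area to
    the distal fix (the fix farthest from the capture area), in (-pi, pi].
    """

    trip_id: str
    bird_id: str
    species: str
    year: int
    capture_area: str
    fixes: pd.DataFrame
    complete: bool
    start: pd.Timestamp = field(default=None)
    end: pd.Timestamp = field(default=None)
    duration_h: float = float("nan")
    distal_lat: float = float("nan")
    distal_lon: float = float("nan")
    distal_distance_km: float = float("nan")
    bearing_rad: float = float("nan")

    def __len__(self) -> int:
        return len(self.fixes)


def trip_summary(trip: Trip, site: SiteRegistry) -> Trip:
    """Fill in a trip's derived fields from its fixes.

    The distal fix maximises great-circle distance from the bird's capture
    area (ties broken by the earlier fix); the trip bearing points from the
    capture area to that fix. Returns a new Trip.
    """
    if trip.fixes.empty:
        raise ValueError(f"trip {trip.trip_id} has no fixes")
    lat0, lon0 = site.location(trip.capture_area)
    lats = trip.fixes["lat"].to_numpy()
    lons = trip.fixes["lon"].to_numpy()
    dists = haversine_km(lat0, lon0, lats, lons)
    k = int(np.argmax(dists))  # argmax returns the first (earliest) maximiser
    start = trip.start if trip.start is not None else trip.fixes["timestamp"].iloc[0]
    end = trip.end if trip.end is not None else trip.fixes["timestamp"].iloc[-1]
    return replace(
        trip,
        start=start,
        end=end,
        duration_h=(end - start).total_seconds() / 3600.0,
        distal_lat=float(lats[k]),
        distal_lon=float(lons[k]),
        distal_distance_km=float(dists[k]),
        bearing_rad=float(initial_bearing_rad(lat0, lon0, lats[k], lons[k])),
    )


def split_trips(
    segment: pd.DataFrame,
    site: SiteRegistry,
    min_dist_m: float | None = None,
    min_duration_s: float = MIN_TRIP_DURATION_S,
    include_bounding_fixes: bool = True,
) -> list[Trip]:
    """Split one track segment into foraging trips.

    Away-runs whose first-to-last timestamp span is under ``min_duration_s``
    are discarded as bathing/preening movements. ``min_dist_m`` defaults to
    the registry's buffer radius. Fixes of a single bird/segment expected.
    """
    if segment.empty:
        return []
    if min_dist_m is None:
        min_dist_m = site.buffer_radius_m
    bird = segment["bird_id"].iloc[0]
    area = segment["capture_area"].iloc[0]
    lat0, lon0 = site.location(area)

    seg = segment.reset_index(drop=True)
    away = (
        haversine_km(lat0, lon0, seg["lat"].to_numpy(), seg["lon"].to_numpy()) * 1000.0
        > min_dist_m
    )
    trips: list[Trip] = []
    n = len(seg)
    i = 0
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        span = (seg["timestamp"].iloc[j] - seg["timestamp"].iloc[i]).total_seconds()
        if span >= min_duration_s:
            has_pre = i > 0
            has_post = j < n - 1
            lo = i - 1 if (has_pre and include_bounding_fixes) else i
            hi = j + 1 if (has_post and include_bounding_fixes) else j
            fixes = seg.iloc[lo : hi + 1].reset_index(drop=True)
            start = seg["timestamp"].iloc[i - 1] if has_pre else seg["timestamp"].iloc[i]
            end = seg["timestamp"].iloc[j + 1] if has_post else seg["timestamp"].iloc[j]
            seg_id = seg["segment_id"].iloc[i] if "segment_id" in seg.columns else 0
            trip = Trip(
                trip_id=f"{bird}-{seg_id}-{len(trips)}",
                bird_id=bird,
                species=seg["species"].iloc[0],
                year=int(seg["year"].iloc[0]),
                capture_area=area,
                fixes=fixes,
                complete=bool(has_pre and has_post),
                start=start,
                end=end,
            )
            trips.append(trip_summary(trip, site))
        i = j + 1
    return trips


def assign_trips(cleaned: pd.DataFrame, site: SiteRegistry, **kwargs) -> list[Trip]:
    """Run trip assignment on every (bird, segment) of a cleaned fix table."""
    trips: list[Trip] = []
    group_cols = ["bird_id", "segment_id"] if "segment_id" in cleaned.columns else ["bird_id"]
    for _, seg in cleaned.groupby(group_cols, sort=True):
        trips.extend(split_trips(seg, site, **kwargs))
    return trips


def filter_complete(trips: list[Trip]) -> list[Trip]:
    """Retain only complete trips (observed leaving and returning)."""
    return [t for t in trips if t.complete]


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """Per-trip summary table (one row per trip, no fixes)."""
    return pd.DataFrame(
        [
            {
                "trip_id": t.trip_id,
                "bird_id": t.bird_id,
                "species": t.species,
                "year": t.year,
                "capture_area": t.capture_area,
                "start": t.start,
                "end": t.end,
                "duration_h": t.duration_h,
                "n_fixes": len(t),
                "complete": t.complete,
                "distal_lat": t.distal_lat,
                "distal_lon": t.distal_lon,
                "distal_distance_km": t.distal_distance_km,
                "bearing_rad": t.bearing_rad,
            }
            for t in trips
        ]
    )
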