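"""Subsampling of trips to a common fix interval.

Tags differ in their sampling schedules (1–10 min between fixes), which
would bias pairwise route-similarity metrics toward densely sampled trips.
Before metric computation every trip is therefore subsampled to a common
interval (default 10 min) with a tolerance window (default ±60 s), using a
greedy forward scan: keep the first fix; thereafter keep the earliest fix
whose gap from the last kept fix falls inside the window; a gap beyond the
window restarts the clock at the next available fix.
"""
from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .errors import ConfigError
from .io import SiteRegistry
from .trips import Trip, trip_summary

DEFAULT_INTERVAL_S = 600.0
DEFAULT_TOLERANCE_S = 60.0


def resample_fixes(
    fixes: pd.DataFrame,
    interval_s: float = DEFAULT_INTERVAL_S,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> pd.DataFrame:
    """Greedy fixed-interval subsample of an ordered fix table."""
    if interval_s <= tolerance_s:
        raise ConfigError("resample interval must exceed its tolerance")
    if fixes.empty:
        return fixes
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    lo, hi = interval_s - tolerance_s, interval_s + tolerance_s
    keep = [0]
    last = t[0]
    for i in range(1, len(t)):
        gap = t[i] - last
        if gap < lo:
            continue
        # inside the window, or past it (restart): either way this fix is kept
        keep.append(i)
        last = t[i]
    return fixes.iloc[keep].reset_index(drop=True)


def resample_trip(
    trip: Trip,
    site: SiteRegistry,
    interval_s: float = DEFAULT_INTERVAL_S,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> Trip:
    """Subsample a trip and recompute its derived summaries.

    The distal fix and bearing are recomputed on the subsampled fixes (the
    original distal fix may have been dropped); trip start/end instants are
    kept from the full-resolution trip so durations are unaffected.
    """
    fixes = resample_fixes(trip.fixes, interval_s, tolerance_s)
    return trip_summary(replace(trip, fixes=fixes), site)
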