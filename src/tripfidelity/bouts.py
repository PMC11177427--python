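"""Foraging-bout detection from dive records and trip-level effort metrics.

A time-depth recorder samples depth every few seconds while the bird is
submerged below 1 m. Consecutive dive records separated by less than five
minutes belong to the same foraging bout; a bout's duration runs from its
first to its last record. Four per-trip effort metrics summarise foraging:
time to first bout (search efficiency), mean bout duration (within-patch
efficiency), total foraging time, and the proportion of the trip spent
foraging.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import fidelity_triple
from .io import SiteRegistry
from .trips import Trip

BOUT_GAP_S = 300.0

EFFORT_COLUMNS = (
    "time_to_first_bout_min",
    "mean_bout_duration_min",
    "total_foraging_min",
    "prop_foraging",
)


def detect_bouts(tdr: pd.DataFrame, gap_s: float = BOUT_GAP_S) -> pd.DataFrame:
    """Group dive records into foraging bouts.

    Records of one bird separated by strictly less than ``gap_s`` seconds
    join the same bout; a gap of exactly ``gap_s`` splits. Returns one row
    per bout: bird_id, start, end, duration_min, n_records.
    """
    rows = []
    for bird, grp in tdr.groupby("bird_id", sort=True):
        t = grp["timestamp"].sort_values().reset_index(drop=True)
        if t.empty:
            continue
        gaps = t.diff().dt.total_seconds()
        new_bout = gaps.isna() | (gaps >= gap_s)
        bout_id = new_bout.cumsum()
        for _, bt in t.groupby(bout_id):
            rows.append(
                {
                    "bird_id": bird,
                    "start": bt.iloc[0],
                    "end": bt.iloc[-1],
                    "duration_min": (bt.iloc[-1] - bt.iloc[0]).total_seconds() / 60.0,
                    "n_records": len(bt),
                }
            )
    return pd.DataFrame(rows, columns=["bird_id", "start", "end", "duration_min", "n_records"])


def classify_foraging_fixes(fixes: pd.DataFrame, bouts: pd.DataFrame) -> pd.Series:
    """Boolean per fix: does it fall inside a foraging bout (closed interval)?

    Expects fixes at the tag's original resolution (not subsampled) and the
    bouts of the same bird.
    """
    result = pd.Series(False, index=fixes.index)
    for _, bout in bouts.iterrows():
        result |= (fixes["timestamp"] >= bout["start"]) & (fixes["timestamp"] <= bout["end"])
    return result


def trip_effort(trip: Trip, bouts: pd.DataFrame, clip: bool = True) -> dict:
    """The four foraging-effort metrics for one trip.

    A bout belongs to the trip iff its start lies within [trip start, trip
    end]; bouts are not split across trips. With ``clip`` (default) bout
    time past the trip end is excluded from total/proportion. Trips with no
    bouts return missing values.
    """
    mine = bouts[
        (bouts["bird_id"] == trip.bird_id)
        & (bouts["start"] >= trip.start)
        & (bouts["start"] <= trip.end)
    ]
    if mine.empty:
        return {"trip_id": trip.trip_id, **{c: float("nan") for c in EFFORT_COLUMNS}}
    first = mine["start"].min()
    durations = mine["duration_min"]
    if clip:
        clipped_end = mine["end"].clip(upper=trip.end)
        total = float(((clipped_end - mine["start"]).dt.total_seconds() / 60.0).sum())
    else:
        total = float(durations.sum())
    trip_min = (trip.end - trip.start).total_seconds() / 60.0
    return {
        "trip_id": trip.trip_id,
        "time_to_first_bout_min": max(0.0, (first - trip.start).total_seconds() / 60.0),
        "mean_bout_duration_min": float(durations.mean()),
        "total_foraging_min": total,
        "prop_foraging": total / trip_min if trip_min > 0 else float("nan"),
    }


def effort_table(trips: list[Trip], bouts: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
    """Per-trip effort metrics for a list of trips."""
    return pd.DataFrame([trip_effort(t, bouts, clip=clip) for t in trips])


def consecutive_trip_table(
    trips: list[Trip],
    bouts: pd.DataFrame,
    site: SiteRegistry,
    nnd_form: str = "pooled_mean",
) -> pd.DataFrame:
    """Analysis table relating consecutive-trip fidelity to prior effort.

    One row per consecutive same-bird same-year trip pair, carrying the
    fidelity metrics of the pair and the effort metrics of the *first* trip
    (the trip whose foraging experience might drive the next choice).
    """
    by_bird_year: dict[tuple, list[Trip]] = {}
    for t in trips:
        by_bird_year.setdefault((t.bird_id, t.year), []).append(t)
    rows = []
    for (bird, year) in sorted(by_bird_year):
        seq = sorted(by_bird_year[(bird, year)], key=lambda t: t.start)
        for t1, t2 in zip(seq, seq[1:]):
            triple = fidelity_triple(t1, t2, site, nnd_form=nnd_form)
            eff = trip_effort(t1, bouts)
            rows.append(
                {
                    "trip_id_a": t1.trip_id,
                    "trip_id_b": t2.trip_id,
                    "bird_id": bird,
                    "species": t1.species,
                    "year": year,
                    "nnd_km": triple.nnd_km,
                    "distal_km": triple.distal_km,
                    "bearing_diff_rad": triple.bearing_diff_rad,
                    "dstart_min": triple.dstart_min,
                    **{c: eff[c] for c in EFFORT_COLUMNS},
                }
            )
    return pd.DataFrame(rows)
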