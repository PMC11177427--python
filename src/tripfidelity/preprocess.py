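"""Track cleaning and gap-based segmentation for raw GPS fixes.

The cleaning pipeline applies, in a fixed order:

1. deployment-window filter (drop fixes before release / after recapture),
2. plausibility filter (bounding box or max radius from the colony),
3. duplicate-timestamp resolution (one fix kept uniformly at random),
4. removal of consecutive fixes identical in position/altitude/bearing/speed
   but with differing timestamps (a known artefact of some archival tags),
5. an iterative speed filter removing fixes reached at > 30 m/s,
6. splitting per-bird tracks into segments at gaps of more than one hour.

Each rule reports how many rows it removed; the counts reconcile exactly
with the input/output row delta.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geo import haversine_km
from .io import GPS_OPTIONAL

MAX_SPEED_MS = 30.0
MAX_GAP_S = 3600.0
IDENTITY_COLS = ("lat", "lon") + GPS_OPTIONAL


@dataclass
class CleanReport:
    """Row-removal accounting for one cleaning run."""

    input_rows: int = 0
    output_rows: int = 0
    removed_window: int = 0
    removed_bbox: int = 0
    removed_duplicate_timestamp: int = 0
    removed_identical_consecutive: int = 0
    removed_speed: int = 0
    segments_created: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return (
            self.removed_window
            + self.removed_bbox
            + self.removed_duplicate_timestamp
            + self.removed_identical_consecutive
            + self.removed_speed
        )

    def as_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "output_rows": self.output_rows,
            "removed_window": self.removed_window,
            "removed_bbox": self.removed_bbox,
            "removed_duplicate_timestamp": self.removed_duplicate_timestamp,
            "removed_identical_consecutive": self.removed_identical_consecutive,
            "removed_speed": self.removed_speed,
            "segments_created": self.segments_created,
            "notes": list(self.notes),
        }


def window_filter(fixes: pd.DataFrame, windows: dict[str, tuple] | None) -> pd.DataFrame:
    """Keep only fixes inside each bird's deployment window (inclusive).

    ``windows`` maps bird_id to (release, recapture) timestamps; birds
    without an entry, or a ``None`` mapping, pass through unchanged.
    """
    if not windows:
        return fixes
    keep = np.ones(len(fixes), dtype=bool)
    for bird, (release, recapture) in windows.items():
        release = pd.Timestamp(release, tz="UTC") if pd.Timestamp(release).tzinfo is None else pd.Timestamp(release)
        recapture = pd.Timestamp(recapture, tz="UTC") if pd.Timestamp(recapture).tzinfo is None else pd.Timestamp(recapture)
        if release > recapture:
            raise ConfigError(f"deployment window for '{bird}': release after recapture")
        mask = fixes["bird_id"] == bird
        keep &= ~mask | ((fixes["timestamp"] >= release) & (fixes["timestamp"] <= recapture))
    return fixes[keep].reset_index(drop=True)


def bbox_filter(
    fixes: pd.DataFrame,
    bbox: tuple[float, float, float, float] | None = None,
    colony: tuple[float, float] | None = None,
    max_radius_km: float | None = None,
) -> pd.DataFrame:
    """Drop fixes in implausible locations.

    The plausible region is either a (lat_min, lat_max, lon_min, lon_max)
    bounding box or a maximum great-circle radius from the colony. With
    neither given, the filter is a pass-through.
    """
    if bbox is not None:
        lat_min, lat_max, lon_min, lon_max = bbox
        keep = (
            fixes["lat"].between(lat_min, lat_max)
            & fixes["lon"].between(lon_min, lon_max)
        )
    elif colony is not None and max_radius_km is not None:
        dist = haversine_km(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), colony[0], colony[1])
        keep = pd.Series(dist <= max_radius_km, index=fixes.index)
    else:
        return fixes
    return fixes[keep].reset_index(drop=True)


def dedupe_timestamps(fixes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resolve duplicate (bird_id, timestamp) rows by keeping one uniformly.

    Which of the duplicates is "real" cannot be known, so the choice is a
    seeded uniform draw for reproducibility.
    """
    if fixes.empty:
        return fixes
    dup = fixes.duplicated(["bird_id", "timestamp"], keep=False)
    if not dup.any():
        return fixes
    keep_idx = list(fixes.index[~dup])
    for _, group in fixes[dup].groupby(["bird_id", "timestamp"], sort=False):
        keep_idx.append(group.index[rng.integers(len(group))])
    return fixes.loc[sorted(keep_idx)].reset_index(drop=True)


def drop_identical_consecutive(fixes: pd.DataFrame) -> pd.DataFrame:
    """Remove the later fix of any consecutive pair with an identical payload.

    Fixes identical in location (and altitude/bearing/speed where those
    columns exist) but with different timestamps are tag artefacts; scanning
    left-to-right, each fix is compared against its surviving predecessor so
    a whole identical run collapses to its first member. Missing values
    compare equal to missing values.
    """
    cols = [c for c in IDENTITY_COLS if c in fixes.columns]
    keep = np.ones(len(fixes), dtype=bool)
    vals = fixes[cols].to_numpy()
    birds = fixes["bird_id"].to_numpy()
    last_kept: dict[str, int] = {}
    for i in range(len(fixes)):
        b = birds[i]
        j = last_kept.get(b)
        if j is not None:
            a, c = vals[j], vals[i]
            same = np.all((a == c) | (pd.isna(a) & pd.isna(c)))
            if same:
                keep[i] = False
                continue
        last_kept[b] = i
    return fixes[keep].reset_index(drop=True)


def speed_filter(fixes: pd.DataFrame, vmax_ms: float = MAX_SPEED_MS) -> pd.DataFrame:
    """Drop fixes reached by movement faster than ``vmax_ms``.

    Speed is recomputed from positions (great-circle distance over elapsed
    time) rather than read from any tag speed field. The later fix of a
    super-threshold pair is removed and the next fix is re-checked against
    the surviving predecessor, so the output contains no consecutive pair
    exceeding the threshold.
    """
    keep = np.ones(len(fixes), dtype=bool)
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    birds = fixes["bird_id"].to_numpy()
    last_kept: dict[str, int] = {}
    for i in range(len(fixes)):
        b = birds[i]
        j = last_kept.get(b)
        if j is not None:
            dt_s = t[i] - t[j]
            if dt_s <= 0:
                raise RuntimeError("zero/negative time step: run dedupe_timestamps first")
            speed = haversine_km(lat[j], lon[j], lat[i], lon[i]) * 1000.0 / dt_s
            if speed > vmax_ms:
                keep[i] = False
                continue
        last_kept[b] = i
    return fixes[keep].reset_index(drop=True)


def segment_by_gaps(fixes: pd.DataFrame, max_gap_s: float = MAX_GAP_S) -> pd.DataFrame:
    """Assign a per-bird ``segment_id`` splitting at gaps of more than ``max_gap_s``.

    A gap of exactly the threshold does not split (the rule is "more than").
    """
    out = fixes.copy()
    if out.empty:
        out["segment_id"] = pd.Series(dtype=int)
        return out
    gaps = out.groupby("bird_id", sort=False)["timestamp"].diff().dt.total_seconds()
    new_segment = gaps.isna() | (gaps > max_gap_s)
    out["segment_id"] = new_segment.groupby(out["bird_id"], sort=False).cumsum().astype(int) - 1
    return out


def clean_gps(
    fixes: pd.DataFrame,
    rng: np.random.Generator,
    windows: dict | None = None,
    bbox: tuple | None = None,
    colony: tuple[float, float] | None = None,
    max_radius_km: float | None = 500.0,
    vmax_ms: float = MAX_SPEED_MS,
    max_gap_s: float = MAX_GAP_S,
) -> tuple[pd.DataFrame, CleanReport]:
    """Run the full cleaning pipeline in its fixed order and segment the result.

    Returns the cleaned, segmented fixes and a :class:`CleanReport` whose
    per-rule counts reconcile exactly with the row delta. With no colony
    given the plausibility filter is skipped (a note is recorded).
    """
    report = CleanReport(input_rows=len(fixes))
    step = window_filter(fixes, windows)
    report.removed_window = len(fixes) - len(step)

    n = len(step)
    if bbox is None and colony is None:
        report.notes.append("no plausible region supplied; bbox filter skipped")
    step = bbox_filter(step, bbox=bbox, colony=colony, max_radius_km=max_radius_km)
    report.removed_bbox = n - len(step)

    n = len(step)
    step = dedupe_timestamps(step, rng)
    report.removed_duplicate_timestamp = n - len(step)

    n = len(step)
    step = drop_identical_consecutive(step)
    report.removed_identical_consecutive = n - len(step)

    n = len(step)
    step = speed_filter(step, vmax_ms)
    report.removed_speed = n - len(step)

    step = segment_by_gaps(step, max_gap_s)
    report.output_rows = len(step)
    report.segments_created = (
        int(step.groupby("bird_id")["segment_id"].nunique().sum()) if len(step) else 0
    )
    return step, report
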