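"""Readers/writers for the pipeline's tabular formats and the site registry.

GPS and dive (TDR) tables are plain UTF-8 CSV with a header row. Timestamps
are stored at 1-second resolution in UTC; inputs carrying a UTC offset are
converted on read. The site registry (capture-area coordinates, the colony
buffer radius, and per species/year median laying dates) lives in a small
YAML file.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

GPS_REQUIRED = ("bird_id", "species", "year", "capture_area", "timestamp", "lat", "lon")
GPS_OPTIONAL = ("altitude", "bearing", "speed")
TDR_REQUIRED = ("bird_id", "timestamp", "depth")


def _parse_timestamps(raw: pd.Series, source: str) -> pd.Series:
    ts = pd.to_datetime(raw, utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based numbering
        lines = [int(i) + 2 for i in raw.index[bad][:5]]
        raise SchemaError(
            f"{source}: unparseable timestamp at line(s) {lines} "
            f"(first bad value: {raw[bad].iloc[0]!r})"
        )
    return ts.dt.floor("s")


def read_gps(path, schema_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a GPS fix table from CSV.

    Parameters
    ----------
    path
        CSV with a header row.
    schema_map
        Optional mapping from canonical column names (``bird_id``, ``lat``,
        ...) to the names actually used in the file.

    Returns
    -------
    DataFrame sorted by (bird_id, timestamp) with timestamps coerced to UTC
    at 1-second resolution. Optional columns (altitude, bearing, speed) are
    kept when present.
    """
    df = pd.read_csv(path)
    if schema_map:
        df = df.rename(columns={v: k for k, v in schema_map.items()})
    for col in GPS_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    keep = list(GPS_REQUIRED) + [c for c in GPS_OPTIONAL if c in df.columns]
    df = df[keep].copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"], str(path))
    df["bird_id"] = df["bird_id"].astype(str)
    df["species"] = df["species"].astype(str)
    df["capture_area"] = df["capture_area"].astype(str)
    df["year"] = df["year"].astype(int)
    for col in ("lat", "lon"):
        df[col] = df[col].astype(float)
    if (df["lat"].abs() > 90).any():
        raise SchemaError(f"{path}: latitude outside [-90, 90]")
    if (df["lon"].abs() > 180).any():
        raise SchemaError(f"{path}: longitude outside [-180, 180]")
    return df.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_tdr(path) -> pd.DataFrame:
    """Read a time-depth-recorder table from CSV.

    Records at or above 1 m depth are rejected (the logger only records
    genuinely submerged samples); the rejection count is logged. Negative
    depths are a hard error.
    """
    df = pd.read_csv(path)
    for col in TDR_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    df = df[list(TDR_REQUIRED)].copy()
    if df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return df
    df["timestamp"] = _parse_timestamps(df["timestamp"], str(path))
    df["bird_id"] = df["bird_id"].astype(str)
    df["depth"] = df["depth"].astype(float)
    if (df["depth"] < 0).any():
        raise SchemaError(f"{path}: negative depth encountered")
    shallow = int((df["depth"] <= 1.0).sum())
    if shallow:
        logger.info("read_tdr: rejected %d record(s) at depth <= 1 m", shallow)
    df = df[df["depth"] > 1.0]
    return df.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def write_table(table: pd.DataFrame, path) -> None:
    """Write any pipeline table to CSV so that it round-trips losslessly.

    Timestamp columns are serialised as ISO-8601 UTC at 1-second resolution;
    missing optional values become empty cells.
    """
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


@dataclass
class SiteRegistry:
    """Colony geometry and breeding phenology needed by the pipeline.

    Attributes
    ----------
    capture_areas
        Mapping from capture-area name to (lat, lon) in decimal degrees.
    buffer_radius_m
        Radius of the at-colony buffer around each capture area; a bird
        farther than this is "away". 500 m by default, matching the
        trip-splitting convention for cliff-nesting seabirds.
    laying_dates
        Optional median laying date per (species, year); used to express
        trip timing relative to breeding phenology in between-year models.
    """

    capture_areas: dict[str, tuple[float, float]]
    buffer_radius_m: float = 500.0
    laying_dates: dict[tuple[str, int], dt.date] = field(default_factory=dict)

    def __post_init__(self):
        if self.buffer_radius_m <= 0:
            raise ConfigError("buffer_radius_m must be positive")

    def location(self, capture_area: str) -> tuple[float, float]:
        try:
            return self.capture_areas[capture_area]
        except KeyError:
            raise ConfigError(f"capture area '{capture_area}' not in registry") from None

    def laying_date(self, species: str, year: int) -> dt.date | None:
        return self.laying_dates.get((species, int(year)))

    @classmethod
    def from_yaml(cls, path) -> "SiteRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        areas = {
            str(name): (float(loc["lat"]), float(loc["lon"]))
            for name, loc in raw["capture_areas"].items()
        }
        laying: dict[tuple[str, int], dt.date] = {}
        for species, by_year in (raw.get("laying_dates") or {}).items():
            for year, day in by_year.items():
                if isinstance(day, str):
                    day = dt.date.fromisoformat(day)
                laying[(str(species), int(year))] = day
        return cls(
            capture_areas=areas,
            buffer_radius_m=float(raw.get("buffer_radius_m", 500.0)),
            laying_dates=laying,
        )

    def to_yaml(self, path) -> None:
        laying: dict[str, dict[int, str]] = {}
        for (species, year), day in self.laying_dates.items():
            laying.setdefault(species, {})[year] = day.isoformat()
        raw = {
            "buffer_radius_m": self.buffer_radius_m,
            "capture_areas": {
                name: {"lat": lat, "lon": lon}
                for name, (lat, lon) in self.capture_areas.items()
            },
            "laying_dates": laying,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
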