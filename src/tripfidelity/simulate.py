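"""Synthetic multi-colony GPS and dive data with known fidelity structure.

The generator emulates central-place commuting trips of cliff-nesting
seabirds: each bird holds an individual preferred foraging direction (von
Mises around the colony-wide mean, concentration ``kappa_pop`` between
birds) and a preferred distal distance (log-normal, between-bird spread
``distal_log_sd_pop``). Each trip draws a direction around the bird's
preference with concentration ``kappa_ind`` and a distance with per-trip
jitter, commutes out at cruising speed, loiters at the target with
small-step random-walk movement (where dive bouts are planted), and
commutes back; colony-attendance fixes are emitted between trips. Fixes
follow a fixed schedule with Gaussian positional noise.

``kappa_ind`` large relative to the between-bird spread produces the
within-individual similarity the downstream contrast must detect; setting
``kappa_ind = kappa_pop = 0`` and ``distal_log_sd_pop = 0`` makes all trips
exchangeable across birds (the no-fidelity null). A per-day shared
direction blended in with ``social_weight`` couples same-day trips, and a
per-trip random drift of each bird's preference erodes fidelity with time.

Everything derives from a single seeded generator; a fixed seed gives
byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geo import destination_point, haversine_km, initial_bearing_rad
from .io import SiteRegistry

SECONDS_PER_DAY = 86400.0


@dataclass
class SpeciesConfig:
    """Per-species population and movement parameters."""

    name: str
    n_birds: int = 12
    years: tuple[int, ...] = (2021,)
    n_days: int = 3                      # tracked days per bird-year
    trips_per_day: int = 2
    fix_interval_s: float = 300.0        # tag schedule, 1-10 min in practice
    speed_ms: float = 16.0               # commuting flight speed
    distal_log_mean_km: float = math.log(25.0)
    distal_log_sd_pop: float = 0.35      # between-bird spread of preferred distance
    distal_log_sd_trip: float = 0.10     # within-bird per-trip jitter
    kappa_pop: float = 0.7               # concentration of bird preferences about colony mean
    kappa_ind: float = 8.0               # concentration of trips about the bird preference
    has_tdr: bool = True


@dataclass
class SimConfig:
    """Colony-level configuration for one simulated tracking study."""

    species: list[SpeciesConfig] = field(default_factory=lambda: [SpeciesConfig("guillemot")])
    colony_lat: float = 56.185           # Isle of May-like colony
    colony_lon: float = -2.557
    n_capture_areas: int = 2
    capture_area_spread_m: float = 800.0  # offsets stay within ~1 km of the colony
    colony_mean_bearing_rad: float = math.pi / 2.0  # seaward direction
    attendance_min: float = 60.0         # colony attendance between trips
    loiter_min: float = 90.0             # mean time at the foraging target
    loiter_jitter_min: float = 25.0      # per-trip uniform jitter of loiter time
    loiter_step_m: float = 80.0          # random-walk step sd while loitering
    noise_sd_m: float = 25.0             # GPS positional noise
    social_weight: float = 0.0           # 0 = independent, 1 = all same-day trips share a bearing
    drift_sd_rad: float = 0.03           # per-trip AR(1) drift of the preferred bearing
    drift_sd_log_dist: float = 0.02      # per-trip drift of the preferred log-distance
    day_start_hour: float = 4.0
    n_bouts_per_trip: int = 3            # maximum; realized count uniform on 1..max
    bout_duration_s: float = 240.0       # log-scale median duration
    bout_duration_log_sd: float = 0.35   # lognormal spread of bout durations
    vary_bouts: bool = True              # False plants exactly max bouts of fixed length
    inter_bout_gap_s: float = 600.0      # well clear of the 300 s bout-joining rule
    dive_sample_s: float = 4.0
    season_start_doy: int = 152          # ~1 June
    laying_doy: int = 125                # ~5 May median laying date

    def validate(self) -> None:
        for sp in self.species:
            worst_km = math.exp(
                sp.distal_log_mean_km + 3.0 * (sp.distal_log_sd_pop + sp.distal_log_sd_trip)
            )
            trip_s = 2.0 * worst_km * 1000.0 / sp.speed_ms + (
                self.loiter_min + self.loiter_jitter_min
            ) * 60.0
            per_day = sp.trips_per_day * (trip_s + self.attendance_min * 60.0)
            if trip_s > SECONDS_PER_DAY or per_day > 2.0 * SECONDS_PER_DAY:
                raise ConfigError(
                    f"species '{sp.name}': trips too long for the daily schedule "
                    f"at speed {sp.speed_ms} m/s and distance ~{worst_km:.0f} km"
                )
        if not 0.0 <= self.social_weight <= 1.0:
            raise ConfigError("social_weight must lie in [0, 1]")


def _wrap(theta: float) -> float:
    return (theta + math.pi) % (2.0 * math.pi) - math.pi


def _blend_bearing(theta: float, shared: float, weight: float) -> float:
    """Circular blend: direction of the weighted sum of unit vectors."""
    x = (1.0 - weight) * math.sin(theta) + weight * math.sin(shared)
    y = (1.0 - weight) * math.cos(theta) + weight * math.cos(shared)
    if x == 0.0 and y == 0.0:
        return theta
    return math.atan2(x, y)


def _meters_to_deg(dy_m, dx_m, lat):
    dlat = np.asarray(dy_m) / 111_320.0
    dlon = np.asarray(dx_m) / (111_320.0 * math.cos(math.radians(lat)))
    return dlat, dlon


def simulate_population(
    config: SimConfig, seed
) -> tuple[pd.DataFrame, pd.DataFrame, SiteRegistry, dict]:
    """Generate (gps, tdr, site registry, truth) for one synthetic study.

    ``truth`` records per-bird preferences, per-trip realised targets and
    planted dive bouts, and the per-day shared directions — the ground truth
    against which trip assignment, metric behaviour, and bout detection can
    be scored.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # capture areas scattered within ~1 km of the colony centre
    areas: dict[str, tuple[float, float]] = {}
    for k in range(config.n_capture_areas):
        ang = rng.uniform(-math.pi, math.pi)
        r_m = rng.uniform(0.0, config.capture_area_spread_m)
        lat, lon = destination_point(config.colony_lat, config.colony_lon, ang, r_m / 1000.0)
        areas[f"area_{k}"] = (float(lat), float(lon))

    all_years = sorted({y for sp in config.species for y in sp.years})
    laying = {
        (sp.name, y): pd.Timestamp(year=y, month=1, day=1).date()
        + pd.Timedelta(days=config.laying_doy - 1 + offset)
        for offset in [0]
        for sp in config.species
        for y in sp.years
    }
    site = SiteRegistry(capture_areas=areas, buffer_radius_m=500.0, laying_dates=laying)

    # one shared direction per (year, day) drives social coupling across species
    max_days = max(sp.n_days for sp in config.species)
    day_direction = {
        (y, d): float(rng.uniform(-math.pi, math.pi))
        for y in all_years
        for d in range(max_days)
    }

    gps_rows: list[dict] = []
    tdr_rows: list[dict] = []
    truth_birds: dict[str, dict] = {}
    truth_trips: list[dict] = []

    for sp in config.species:
        for b in range(sp.n_birds):
            bird_id = f"{sp.name}_{b:03d}"
            area_name = f"area_{b % config.n_capture_areas}"
            lat0, lon0 = areas[area_name]
            pref_bearing = (
                float(rng.vonmises(config.colony_mean_bearing_rad, sp.kappa_pop))
                if sp.kappa_pop > 0
                else float(rng.uniform(-math.pi, math.pi))
            )
            pref_log_dist = sp.distal_log_mean_km + sp.distal_log_sd_pop * rng.standard_normal()
            truth_birds[bird_id] = {
                "species": sp.name,
                "capture_area": area_name,
                "preferred_bearing_rad": pref_bearing,
                "preferred_log_distance": pref_log_dist,
            }

            for year in sp.years:
                season0 = pd.Timestamp(year=year, month=1, day=1, tz="UTC") + pd.Timedelta(
                    days=config.season_start_doy - 1
                )
                state_bearing = pref_bearing
                state_log_dist = pref_log_dist
                cursor = None
                for day in range(sp.n_days):
                    day_start = (
                        season0
                        + pd.Timedelta(days=day)
                        + pd.Timedelta(
                            seconds=config.day_start_hour * 3600.0 + rng.uniform(0, 3600.0)
                        )
                    )
                    cursor = day_start if cursor is None else max(cursor, day_start)
                    for k in range(sp.trips_per_day):
                        # colony attendance preceding the trip
                        att_end = cursor + pd.Timedelta(minutes=config.attendance_min)
                        t = cursor
                        while t <= att_end:
                            dy, dx = rng.normal(0.0, config.noise_sd_m, size=2)
                            dlat, dlon = _meters_to_deg(dy, dx, lat0)
                            gps_rows.append(
                                dict(bird_id=bird_id, species=sp.name, year=year,
                                     capture_area=area_name, timestamp=t,
                                     lat=lat0 + float(dlat), lon=lon0 + float(dlon))
                            )
                            t = t + pd.Timedelta(seconds=sp.fix_interval_s)

                        # realised trip target
                        mean_bearing = _blend_bearing(
                            state_bearing, day_direction[(year, day)], config.social_weight
                        )
                        trip_bearing = (
                            float(rng.vonmises(mean_bearing, sp.kappa_ind))
                            if sp.kappa_ind > 0
                            else float(rng.uniform(-math.pi, math.pi))
                        )
                        if config.social_weight >= 1.0:
                            trip_bearing = day_direction[(year, day)]
                        dist_km = math.exp(
                            state_log_dist + sp.distal_log_sd_trip * rng.standard_normal()
                        )
                        tgt_lat, tgt_lon = destination_point(lat0, lon0, trip_bearing, dist_km)

                        t_depart = att_end
                        t_out = dist_km * 1000.0 / sp.speed_ms
                        t_arrive = t_depart + pd.Timedelta(seconds=t_out)
                        loiter = config.loiter_min + (
                            rng.uniform(-config.loiter_jitter_min, config.loiter_jitter_min)
                            if config.loiter_jitter_min > 0
                            else 0.0
                        )
                        t_leave = t_arrive + pd.Timedelta(minutes=loiter)
                        t_return = t_leave + pd.Timedelta(seconds=t_out)

                        # fixes along the out-loiter-back path
                        t = t_depart + pd.Timedelta(seconds=sp.fix_interval_s)
                        walk_x = walk_y = 0.0
                        path_true: list[tuple[float, float]] = []
                        while t < t_return:
                            el = (t - t_depart).total_seconds()
                            if t < t_arrive:
                                d = sp.speed_ms * el / 1000.0
                                lat, lon = destination_point(lat0, lon0, trip_bearing, d)
                            elif t <= t_leave:
                                walk_x += rng.normal(0.0, config.loiter_step_m)
                                walk_y += rng.normal(0.0, config.loiter_step_m)
                                dlat, dlon = _meters_to_deg(walk_y, walk_x, tgt_lat)
                                lat, lon = tgt_lat + float(dlat), tgt_lon + float(dlon)
                            else:
                                back = (t_return - t).total_seconds()
                                d = sp.speed_ms * back / 1000.0
                                lat, lon = destination_point(lat0, lon0, trip_bearing, d)
                            path_true.append((float(lat), float(lon)))
                            dy, dx = rng.normal(0.0, config.noise_sd_m, size=2)
                            dlat, dlon = _meters_to_deg(dy, dx, lat)
                            gps_rows.append(
                                dict(bird_id=bird_id, species=sp.name, year=year,
                                     capture_area=area_name, timestamp=t,
                                     lat=float(lat) + float(dlat), lon=float(lon) + float(dlon))
                            )
                            t = t + pd.Timedelta(seconds=sp.fix_interval_s)

                        # realized distal point of the noise-free track: the
                        # ground truth a distal-fix detector can recover
                        tp = np.array(path_true)
                        td = haversine_km(lat0, lon0, tp[:, 0], tp[:, 1])
                        k_max = int(np.argmax(td))
                        realized_bearing = float(
                            initial_bearing_rad(lat0, lon0, tp[k_max, 0], tp[k_max, 1])
                        )
                        realized_distance = float(td[k_max])

                        # planted dive bouts during the loiter phase
                        bout_windows = []
                        if sp.has_tdr and config.n_bouts_per_trip > 0:
                            if config.vary_bouts:
                                n_bouts = int(rng.integers(1, config.n_bouts_per_trip + 1))
                                durations = config.bout_duration_s * np.exp(
                                    config.bout_duration_log_sd
                                    * rng.standard_normal(n_bouts)
                                )
                            else:
                                n_bouts = config.n_bouts_per_trip
                                durations = np.full(n_bouts, config.bout_duration_s)
                            bt = t_arrive + pd.Timedelta(seconds=60.0)
                            for dur in durations:
                                b_end = bt + pd.Timedelta(seconds=float(dur))
                                if b_end > t_leave:
                                    break
                                s = bt
                                last = bt
                                while s <= b_end:
                                    tdr_rows.append(
                                        dict(bird_id=bird_id, timestamp=s,
                                             depth=float(rng.uniform(2.0, 40.0)))
                                    )
                                    last = s
                                    s = s + pd.Timedelta(seconds=config.dive_sample_s)
                                # truth carries the span of the planted records
                                bout_windows.append((bt, last))
                                bt = b_end + pd.Timedelta(seconds=config.inter_bout_gap_s)

                        truth_trips.append(
                            dict(bird_id=bird_id, species=sp.name, year=year, day_index=day,
                                 trip_index=k, target_bearing_rad=trip_bearing,
                                 target_distance_km=dist_km,
                                 realized_bearing_rad=realized_bearing,
                                 realized_distance_km=realized_distance,
                                 t_depart=t_depart, t_return=t_return,
                                 n_bouts=len(bout_windows),
                                 bout_starts=[w[0] for w in bout_windows],
                                 bout_ends=[w[1] for w in bout_windows])
                        )

                        # drift of the preference between trips (fidelity decay)
                        state_bearing = _wrap(
                            state_bearing + config.drift_sd_rad * rng.standard_normal()
                        )
                        state_log_dist += config.drift_sd_log_dist * rng.standard_normal()
                        cursor = t_return

                    # trailing attendance so the day's last trip is complete
                    tail_end = cursor + pd.Timedelta(minutes=15.0)
                    t = cursor
                    while t <= tail_end:
                        dy, dx = rng.normal(0.0, config.noise_sd_m, size=2)
                        dlat, dlon = _meters_to_deg(dy, dx, lat0)
                        gps_rows.append(
                            dict(bird_id=bird_id, species=sp.name, year=year,
                                 capture_area=area_name, timestamp=t,
                                 lat=lat0 + float(dlat), lon=lon0 + float(dlon))
                        )
                        t = t + pd.Timedelta(seconds=sp.fix_interval_s)
                    cursor = tail_end + pd.Timedelta(seconds=sp.fix_interval_s)

    gps = pd.DataFrame(gps_rows)
    gps["timestamp"] = gps["timestamp"].dt.floor("s")
    gps = gps.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    tdr = pd.DataFrame(tdr_rows, columns=["bird_id", "timestamp", "depth"])
    if not tdr.empty:
        tdr["timestamp"] = tdr["timestamp"].dt.floor("s")
        tdr = tdr.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    truth = {
        "birds": truth_birds,
        "trips": truth_trips,
        "day_direction": day_direction,
    }
    return gps, tdr, site, truth


def expected_min_circular_difference(kappa: float, n_draws: int = 200_000, seed: int = 0) -> float:
    """Expected minimal circular difference between two von Mises draws.

    Monte-Carlo estimate of E[min(|a-b|, 2*pi-|a-b|)] for a, b independent
    VM(0, kappa); for kappa = 0 (uniform bearings) the closed form is pi/2.
    """
    if kappa == 0:
        return math.pi / 2.0
    rng = np.random.default_rng(seed)
    a = rng.vonmises(0.0, kappa, n_draws)
    b = rng.vonmises(0.0, kappa, n_draws)
    d = np.abs(a - b) % (2.0 * math.pi)
    return float(np.minimum(d, 2.0 * math.pi - d).mean())


def planted_expectations(truth: dict, config: SimConfig) -> dict:
    """Summaries the pipeline should recover from a simulated dataset."""
    trips = truth["trips"]
    per_bird: dict[str, int] = {}
    for t in trips:
        per_bird[t["bird_id"]] = per_bird.get(t["bird_id"], 0) + 1
    by_species = {sp.name: sp for sp in config.species}
    exp_within = {
        name: expected_min_circular_difference(sp.kappa_ind)
        for name, sp in by_species.items()
    }
    return {
        "n_trips_total": len(trips),
        "n_trips_per_bird": per_bird,
        "n_bouts_per_trip": {f"{t['bird_id']}:{t['year']}:{t['day_index']}:{t['trip_index']}": t["n_bouts"]
                             for t in trips},
        "expected_within_bearing_diff_rad": exp_within,
    }
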