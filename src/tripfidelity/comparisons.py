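"""Comparison designs: within-individual pairs vs between-individual nulls.

Fidelity is detected by contrasting an empirical distribution (trip pairs
from the same individual) against a null (pairs from different individuals
of the same species), with the null sample sized to match the empirical one
per focal unit so individuals with more trips carry proportionally more
weight. Three designs are provided:

* within-year — all same-bird same-year pairs vs equal-count samples from
  other conspecifics tracked that year;
* between-year — all cross-year same-bird pairs vs equal-count samples
  pairing the focal bird's earlier-year trips with other conspecifics
  tracked in the later year;
* same-day — one trip per individual per day, comparing within-species /
  between-species trips made on the same vs on a different day.

Between-unit sampling is uniform over (other-bird, trip) pairs, without
replacement when the candidate pool suffices and with replacement
otherwise (logged). All randomness flows through the supplied generator,
so a fixed seed reproduces the table exactly.
"""
from __future__ import annotations

import itertools
import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .io import SiteRegistry
from .metrics import fidelity_triple
from .trips import Trip

logger = logging.getLogger(__name__)


def _sample(pool: list, n: int, rng: np.random.Generator, stratum: str) -> list:
    if n <= 0 or not pool:
        return []
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    else:
        logger.info("stratum %s: pool of %d < %d draws; sampling with replacement", stratum, len(pool), n)
        idx = rng.choice(len(pool), size=n, replace=True)
    return [pool[i] for i in idx]


def _record(trip_a: Trip, trip_b: Trip, site: SiteRegistry, nnd_form: str, **extra) -> dict:
    triple = fidelity_triple(trip_a, trip_b, site, nnd_form=nnd_form)
    rec = {
        "trip_id_a": trip_a.trip_id,
        "trip_id_b": trip_b.trip_id,
        "bird_a": trip_a.bird_id,
        "bird_b": trip_b.bird_id,
        "species_a": trip_a.species,
        "species_b": trip_b.species,
        "year_a": trip_a.year,
        "year_b": trip_b.year,
        "nnd_km": triple.nnd_km,
        "distal_km": triple.distal_km,
        "bearing_diff_rad": triple.bearing_diff_rad,
        "capture_dist_m": triple.capture_dist_m,
        "dstart_min": triple.dstart_min,
    }
    rec.update(extra)
    return rec


def _sorted_trips(trips: list[Trip]) -> list[Trip]:
    return sorted(trips, key=lambda t: (t.bird_id, t.start, t.trip_id))


def within_year_design(
    trips: list[Trip],
    site: SiteRegistry,
    rng: np.random.Generator,
    nnd_form: str = "pooled_mean",
) -> pd.DataFrame:
    """Within-year fidelity comparison table.

    Focal units are bird-years with at least two complete trips. All
    unordered same-bird pairs form the within-individual rows; for each such
    pair one between-individual row pairs the earlier focal trip with a trip
    drawn from other conspecifics tracked the same year.
    """
    by_group: dict[tuple, dict[str, list[Trip]]] = defaultdict(lambda: defaultdict(list))
    for t in _sorted_trips(trips):
        by_group[(t.species, t.year)][t.bird_id].append(t)

    records = []
    for (species, year) in sorted(by_group):
        birds = by_group[(species, year)]
        for bird in sorted(birds):
            own = birds[bird]
            if len(own) < 2:
                continue
            within_pairs = list(itertools.combinations(own, 2))
            pool = [t for b, ts in birds.items() if b != bird for t in ts]
            if not pool:
                logger.warning(
                    "within_year: %s/%s %s has no conspecific comparators; "
                    "within pairs only",
                    species, year, bird,
                )
            comps = _sample(pool, len(within_pairs), rng, f"{species}/{year}/{bird}")
            for (ta, tb) in within_pairs:
                records.append(
                    _record(ta, tb, site, nnd_form,
                            design="within_year", comparison_type="within_individual")
                )
            for (ta, _), tc in zip(within_pairs, comps):
                records.append(
                    _record(ta, tc, site, nnd_form,
                            design="within_year", comparison_type="between_individual")
                )
    return pd.DataFrame(records)


def _laying_offset(trip: Trip, site: SiteRegistry) -> float:
    lay = site.laying_date(trip.species, trip.year)
    if lay is None:
        return float("nan")
    return (trip.start.date() - lay).days


def between_year_design(
    trips: list[Trip],
    site: SiteRegistry,
    rng: np.random.Generator,
    nnd_form: str = "pooled_mean",
) -> pd.DataFrame:
    """Between-year fidelity comparison table.

    For each bird tracked in two (or more) years, every earlier-year trip is
    paired with every later-year trip (within-individual); an equal-sized
    between-individual sample pairs the focal earlier-year trips with trips
    from other conspecifics tracked in the later year. ``delta_laying_days``
    is the difference in trip timing relative to each year's median laying
    date; it is missing (and flagged) when a laying date is unknown.
    """
    by_species: dict[str, dict[str, dict[int, list[Trip]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(list))
    )
    for t in _sorted_trips(trips):
        by_species[t.species][t.bird_id][t.year].append(t)

    records = []
    for species in sorted(by_species):
        birds = by_species[species]
        for bird in sorted(birds):
            years = sorted(birds[bird])
            if len(years) < 2:
                continue
            for y1, y2 in itertools.combinations(years, 2):
                within_pairs = list(itertools.product(birds[bird][y1], birds[bird][y2]))
                pool = [
                    t for b, by_year in birds.items() if b != bird
                    for t in by_year.get(y2, [])
                ]
                if not pool:
                    logger.warning(
                        "between_year: %s %s %d->%d has no conspecific comparators",
                        species, bird, y1, y2,
                    )
                comps = _sample(pool, len(within_pairs), rng, f"{species}/{bird}/{y1}-{y2}")

                def _extra(ta, tb, ctype):
                    off_a = _laying_offset(ta, site)
                    off_b = _laying_offset(tb, site)
                    return dict(
                        design="between_year",
                        comparison_type=ctype,
                        delta_years=abs(tb.year - ta.year),
                        delta_laying_days=abs(off_a - off_b),
                        laying_missing=bool(np.isnan(off_a) or np.isnan(off_b)),
                    )

                for (ta, tb) in within_pairs:
                    records.append(
                        _record(ta, tb, site, nnd_form, **_extra(ta, tb, "within_individual"))
                    )
                for (ta, _), tc in zip(within_pairs, comps):
                    records.append(
                        _record(ta, tc, site, nnd_form, **_extra(ta, tc, "between_individual"))
                    )
    return pd.DataFrame(records)


def same_day_design(
    trips: list[Trip],
    site: SiteRegistry,
    rng: np.random.Generator,
    nnd_form: str = "pooled_mean",
) -> pd.DataFrame:
    """Short-timescale similarity table: same-day vs different-day pairs.

    Per species x year x day one trip per individual is sampled (trips
    spanning midnight are eligible via their start date, so longer trips are
    not excluded). Within-day rows compare those trips within species (all
    pairs) and to one sampled trip of each other species; between-day rows
    repeat both comparisons against trips from one alternative day of the
    same year, giving equal within-/between-day counts per day.
    """
    sampled: dict[tuple[str, int], dict[object, list[Trip]]] = defaultdict(lambda: defaultdict(list))
    by_day_bird: dict[tuple, dict[str, list[Trip]]] = defaultdict(lambda: defaultdict(list))
    for t in _sorted_trips(trips):
        by_day_bird[(t.species, t.year, t.start.date())][t.bird_id].append(t)
    for (species, year, day) in sorted(by_day_bird):
        for bird in sorted(by_day_bird[(species, year, day)]):
            own = by_day_bird[(species, year, day)][bird]
            pick = own[int(rng.integers(len(own)))]
            sampled[(species, year)][day].append(pick)

    records = []
    for (species, year) in sorted(sampled):
        days = sampled[(species, year)]
        # ordered species pairs so an unordered cross-species pair is built once
        other_species = sorted(
            sp for (sp, yr) in sampled if yr == year and sp > species
        )
        for day in sorted(days):
            todays = days[day]
            # alternative day for the between-day comparisons of this stratum
            alt_days = [d for d in sorted(days) if d != day]
            alt_day = alt_days[int(rng.integers(len(alt_days)))] if alt_days else None

            within_day_pairs = list(itertools.combinations(todays, 2))
            extra = dict(design="same_day", day=day, species_match="within_species")
            for (ta, tb) in within_day_pairs:
                records.append(
                    _record(ta, tb, site, nnd_form, day_match="within_day", **extra)
                )
            if alt_day is not None:
                alt_pool = days[alt_day]
                for (ta, _tb) in within_day_pairs:
                    # the other-day comparator comes from a different bird, so
                    # the day contrast is not diluted by individual fidelity
                    candidates = [t for t in alt_pool if t.bird_id != ta.bird_id]
                    if not candidates:
                        logger.info(
                            "same_day: %s/%s %s alt-day pool holds only the focal "
                            "bird; allowing a cross-day self-comparison",
                            species, year, day,
                        )
                        candidates = alt_pool
                    tc = candidates[int(rng.integers(len(candidates)))]
                    records.append(
                        _record(ta, tc, site, nnd_form, day_match="between_day", **extra)
                    )

            for other in other_species:
                other_days = sampled[(other, year)]
                if day not in other_days:
                    continue
                x_extra = dict(design="same_day", day=day, species_match="between_species")
                pool = other_days[day]
                cross = []
                for ta in todays:
                    tc = pool[int(rng.integers(len(pool)))]
                    cross.append(ta)
                    records.append(
                        _record(ta, tc, site, nnd_form, day_match="within_day", **x_extra)
                    )
                alt_other = [d for d in sorted(other_days) if d != day]
                if alt_other:
                    d2 = alt_day if (alt_day in other_days) else alt_other[int(rng.integers(len(alt_other)))]
                    pool2 = other_days[d2]
                    for ta in cross:
                        tc = pool2[int(rng.integers(len(pool2)))]
                        records.append(
                            _record(ta, tc, site, nnd_form, day_match="between_day", **x_extra)
                        )
    return pd.DataFrame(records)
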