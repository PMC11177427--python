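import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from tripfidelity import between_year_design, same_day_design, within_year_design
from tripfidelity.io import SiteRegistry

from conftest import COLONY, make_trip


def _trips(site, spec):
    """spec: list of (bird, n_trips, year, day_offset[, species]) tuples."""
    out = []
    for row in spec:
        bird, n, year, day = row[:4]
        species = row[4] if len(row) > 4 else "guillemot"
        for k in range(n):
            start = f"{year}-06-{1 + day:02d} {6 + 3 * k:02d}:00:00"
            out.append(
                make_trip(
                    site, f"{bird}-{year}-{day}-{k}", bird,
                    bearing_rad=0.1 * k, dist_km=20 + k, start=start,
                    species=species, year=year, duration_h=2.0,
                )
            )
    return out


class TestWithinYear:
    def test_three_trips_give_three_within_and_three_between(self, site):
        trips = _trips(site, [("f", 3, 2021, 0), ("o", 2, 2021, 1)])
        tab = within_year_design(trips, site, np.random.default_rng(0))
        f = tab[tab.bird_a == "f"]
        assert (f.comparison_type == "within_individual").sum() == 3
        assert (f.comparison_type == "between_individual").sum() == 3
        between = f[f.comparison_type == "between_individual"]
        assert (between.bird_b == "o").all()

    def test_single_trip_bird_is_not_focal(self, site):
        trips = _trips(site, [("f", 1, 2021, 0), ("o", 3, 2021, 1)])
        tab = within_year_design(trips, site, np.random.default_rng(0))
        assert "f" not in set(tab.bird_a)
        # but its trip is a candidate comparator
        assert "f" in set(tab.bird_b)

    def test_two_birds_two_trips_each(self, site):
        trips = _trips(site, [("a", 2, 2021, 0), ("b", 2, 2021, 1)])
        tab = within_year_design(trips, site, np.random.default_rng(0))
        assert len(tab) == 4
        counts = tab.groupby(["bird_a", "comparison_type"]).size()
        assert (counts == 1).all()

    def test_no_cross_species_or_cross_year_pairs(self, site):
        trips = _trips(
            site,
            [("a", 2, 2021, 0), ("b", 2, 2021, 1),
             ("c", 2, 2020, 0), ("p", 2, 2021, 0, "puffin")],
        )
        tab = within_year_design(trips, site, np.random.default_rng(0))
        assert (tab.species_a == tab.species_b).all()
        assert (tab.year_a == tab.year_b).all()

    def test_no_self_or_duplicate_pairs(self, site):
        trips = _trips(site, [("a", 4, 2021, 0), ("b", 3, 2021, 1)])
        tab = within_year_design(trips, site, np.random.default_rng(1))
        assert (tab.trip_id_a != tab.trip_id_b).all()
        within = tab[tab.comparison_type == "within_individual"]
        keys = within.apply(lambda r: frozenset((r.trip_id_a, r.trip_id_b)), axis=1)
        assert keys.is_unique

    def test_seed_reproducibility_and_scope(self, site):
        trips = _trips(site, [("a", 3, 2021, 0), ("b", 3, 2021, 1), ("c", 3, 2021, 2)])
        t1 = within_year_design(trips, site, np.random.default_rng(5))
        t2 = within_year_design(trips, site, np.random.default_rng(5))
        t3 = within_year_design(trips, site, np.random.default_rng(6))
        pd.testing.assert_frame_equal(t1, t2)
        w1 = t1[t1.comparison_type == "within_individual"].reset_index(drop=True)
        w3 = t3[t3.comparison_type == "within_individual"].reset_index(drop=True)
        pd.testing.assert_frame_equal(w1, w3)  # only between rows depend on the seed


class TestBetweenYear:
    def test_two_years_two_trips_each(self, site):
        trips = _trips(
            site, [("f", 2, 2020, 0), ("f", 2, 2021, 0), ("o", 3, 2021, 1)]
        )
        tab = between_year_design(trips, site, np.random.default_rng(0))
        f = tab[tab.bird_a == "f"]
        assert (f.comparison_type == "within_individual").sum() == 4
        assert (f.comparison_type == "between_individual").sum() == 4
        between = f[f.comparison_type == "between_individual"]
        assert (between.bird_b == "o").all()
        assert (between.year_b == 2021).all()

    def test_delta_years(self, site):
        trips = _trips(
            site, [("f", 1, 2010, 0), ("f", 1, 2013, 0), ("o", 1, 2013, 1)]
        )
        tab = between_year_design(trips, site, np.random.default_rng(0))
        assert set(tab.delta_years) == {3}

    def test_missing_laying_date_flagged(self, site):
        site.laying_dates = {("guillemot", 2020): dt.date(2020, 5, 5)}
        trips = _trips(
            site, [("f", 1, 2020, 0), ("f", 1, 2021, 0), ("o", 1, 2021, 1)]
        )
        tab = between_year_design(trips, site, np.random.default_rng(0))
        assert tab.laying_missing.all()
        assert tab.delta_laying_days.isna().all()

    def test_laying_offsets_differenced(self, site):
        site.laying_dates = {
            ("guillemot", 2020): dt.date(2020, 5, 1),
            ("guillemot", 2021): dt.date(2021, 5, 11),
        }
        trips = _trips(
            site, [("f", 1, 2020, 0), ("f", 1, 2021, 0), ("o", 1, 2021, 1)]
        )
        tab = between_year_design(trips, site, np.random.default_rng(0))
        # focal trips start June 1: offsets 31 (2020) vs 21 (2021) -> |diff| = 10;
        # the comparison bird departs June 2 (offset 22) -> |31 - 22| = 9
        within = tab[tab.comparison_type == "within_individual"]
        between = tab[tab.comparison_type == "between_individual"]
        assert set(within.delta_laying_days) == {10.0}
        assert set(between.delta_laying_days) == {9.0}

    def test_single_year_bird_contributes_nothing(self, site):
        trips = _trips(site, [("f", 3, 2021, 0), ("o", 3, 2021, 1)])
        tab = between_year_design(trips, site, np.random.default_rng(0))
        assert tab.empty


class TestSameDay:
    def test_three_birds_one_day(self, site):
        trips = _trips(site, [("a", 1, 2021, 0), ("b", 1, 2021, 0), ("c", 1, 2021, 0)])
        tab = same_day_design(trips, site, np.random.default_rng(0))
        w = tab[(tab.species_match == "within_species") & (tab.day_match == "within_day")]
        assert len(w) == 3  # C(3,2)
        # single day: no between-day analogues possible
        assert (tab.day_match == "within_day").all()

    def test_one_bird_per_species_gives_one_cross_pair(self, site):
        trips = _trips(
            site, [("a", 1, 2021, 0), ("k", 1, 2021, 0, "kittiwake")]
        )
        tab = same_day_design(trips, site, np.random.default_rng(0))
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.species_match == "between_species"
        assert {row.species_a, row.species_b} == {"guillemot", "kittiwake"}

    def test_equal_within_and_between_day_counts(self, site):
        trips = _trips(
            site,
            [("a", 1, 2021, 0), ("b", 1, 2021, 0), ("c", 1, 2021, 0),
             ("a", 1, 2021, 1), ("b", 1, 2021, 1)],
        )
        tab = same_day_design(trips, site, np.random.default_rng(0))
        counts = (
            tab[tab.species_match == "within_species"]
            .groupby(["day", "day_match"]).size().unstack(fill_value=0)
        )
        assert (counts["within_day"] == counts["between_day"]).all()

    def test_one_trip_sampled_per_individual_per_day(self, site):
        trips = _trips(site, [("a", 4, 2021, 0), ("b", 4, 2021, 0)])
        tab = same_day_design(trips, site, np.random.default_rng(2))
        # only one (a, b) pair possible per day despite 4 trips each
        assert len(tab) == 1


def test_designs_balance_property(site):
    """Equal within/between counts per focal unit over random datasets."""
    rng = np.random.default_rng(99)
    for rep in range(8):
        spec = []
        for b in range(rng.integers(2, 6)):
            spec.append((f"b{b}", int(rng.integers(1, 5)), 2021, int(rng.integers(0, 3))))
        trips = _trips(site, spec)
        tab = within_year_design(trips, site, rng)
        if tab.empty:
            continue
        counts = tab.groupby(["bird_a", "comparison_type"]).size().unstack(fill_value=0)
        assert (counts["within_individual"] == counts["between_individual"]).all()
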