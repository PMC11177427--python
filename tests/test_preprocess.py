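import numpy as np
import pandas as pd
import pytest

from tripfidelity.errors import ConfigError
from tripfidelity.geo import destination_point, haversine_km
from tripfidelity.preprocess import (
    bbox_filter,
    clean_gps,
    dedupe_timestamps,
    drop_identical_consecutive,
    segment_by_gaps,
    speed_filter,
    window_filter,
)

from conftest import COLONY, make_fixes


def _at(dist_km, bearing=0.0):
    la, lo = destination_point(COLONY[0], COLONY[1], bearing, dist_km)
    return float(la), float(lo)


class TestWindowFilter:
    def test_boundary_inclusive(self):
        fixes = make_fixes("b1", [-5, 0, 10], [56.0] * 3, [-2.0] * 3)
        t0 = fixes["timestamp"].iloc[1]
        t1 = fixes["timestamp"].iloc[2]
        out = window_filter(fixes, {"b1": (t0, t1)})
        assert list(out["timestamp"]) == [t0, t1]

    def test_no_window_pass_through(self):
        fixes = make_fixes("b1", [0, 10], [56.0, 56.1], [-2.0, -2.1])
        pd.testing.assert_frame_equal(window_filter(fixes, None), fixes)

    def test_inverted_window_errors(self):
        fixes = make_fixes("b1", [0], [56.0], [-2.0])
        t = fixes["timestamp"].iloc[0]
        with pytest.raises(ConfigError):
            window_filter(fixes, {"b1": (t + pd.Timedelta("1h"), t)})


class TestBboxFilter:
    def test_far_fix_removed_by_radius(self):
        near = _at(10.0)
        far = _at(2000.0)
        fixes = make_fixes("b1", [0, 600], [near[0], far[0]], [near[1], far[1]])
        out = bbox_filter(fixes, colony=COLONY, max_radius_km=500.0)
        assert len(out) == 1

    def test_all_inside_unchanged(self):
        fixes = make_fixes("b1", [0, 600], [56.0, 56.1], [-2.0, -2.1])
        pd.testing.assert_frame_equal(
            bbox_filter(fixes, colony=COLONY, max_radius_km=500.0), fixes
        )

    def test_region_omitted_pass_through(self):
        fixes = make_fixes("b1", [0], [10.0], [100.0])
        pd.testing.assert_frame_equal(bbox_filter(fixes), fixes)


class TestDedupe:
    def test_duplicate_resolution_is_seeded(self):
        fixes = make_fixes("b1", [0, 0, 600], [56.0, 56.5, 56.1], [-2.0, -2.5, -2.1])
        out1 = dedupe_timestamps(fixes, np.random.default_rng(7))
        out2 = dedupe_timestamps(fixes, np.random.default_rng(7))
        assert len(out1) == 2
        pd.testing.assert_frame_equal(out1, out2)

    def test_no_duplicates_unchanged(self):
        fixes = make_fixes("b1", [0, 600], [56.0, 56.1], [-2.0, -2.1])
        pd.testing.assert_frame_equal(
            dedupe_timestamps(fixes, np.random.default_rng(0)), fixes
        )

    def test_three_way_duplicate_uniform(self):
        fixes = make_fixes("b1", [0, 0, 0], [56.0, 56.1, 56.2], [-2.0, -2.1, -2.2])
        rng = np.random.default_rng(123)
        counts = np.zeros(3)
        n = 4000
        for _ in range(n):
            kept = dedupe_timestamps(fixes, rng)
            counts[[56.0, 56.1, 56.2].index(kept["lat"].iloc[0])] += 1
        assert np.all(np.abs(counts / n - 1 / 3) < 0.03)


def _scan_oracle(df, cols):
    """Brute-force reference scan for the identical-consecutive rule."""
    kept = []
    for _, row in df.iterrows():
        if kept and all(
            (row[c] == kept[-1][c]) or (pd.isna(row[c]) and pd.isna(kept[-1][c]))
            for c in cols
        ):
            continue
        kept.append(row)
    return pd.DataFrame(kept).reset_index(drop=True)


class TestIdenticalConsecutive:
    def test_pair_collapses(self):
        fixes = make_fixes("b1", [0, 60], [56.0, 56.0], [-2.0, -2.0])
        assert len(drop_identical_consecutive(fixes)) == 1

    def test_run_collapses_to_first(self):
        fixes = make_fixes("b1", [0, 60, 120], [56.0] * 3, [-2.0] * 3)
        out = drop_identical_consecutive(fixes)
        oracle = _scan_oracle(fixes, ["lat", "lon"])
        assert len(out) == 1
        pd.testing.assert_frame_equal(out, oracle)

    def test_non_consecutive_repeat_kept(self):
        fixes = make_fixes("b1", [0, 60, 120], [56.0, 56.5, 56.0], [-2.0, -2.5, -2.0])
        assert len(drop_identical_consecutive(fixes)) == 3

    def test_nan_optionals_compare_equal(self):
        fixes = make_fixes(
            "b1", [0, 60], [56.0, 56.0], [-2.0, -2.0], altitude=[np.nan, np.nan]
        )
        assert len(drop_identical_consecutive(fixes)) == 1

    def test_random_streams_match_oracle(self):
        rng = np.random.default_rng(5)
        lat_pool = [56.0, 56.1]
        fixes = make_fixes(
            "b1",
            np.arange(40) * 60,
            rng.choice(lat_pool, 40),
            [-2.0] * 40,
        )
        out = drop_identical_consecutive(fixes)
        pd.testing.assert_frame_equal(out, _scan_oracle(fixes, ["lat", "lon"]))


class TestSpeedFilter:
    def test_fast_pair_drops_second(self):
        a = _at(0.0)
        b = _at(36.0)  # 36 km in 600 s = 60 m/s
        fixes = make_fixes("b1", [0, 600], [a[0], b[0]], [a[1], b[1]])
        out = speed_filter(fixes)
        assert len(out) == 1 and out["lat"].iloc[0] == a[0]

    def test_slow_track_unchanged(self):
        pts = [_at(d) for d in [0, 5, 10]]  # 5 km per 600 s ~ 8.3 m/s
        fixes = make_fixes("b1", [0, 600, 1200], [p[0] for p in pts], [p[1] for p in pts])
        pd.testing.assert_frame_equal(speed_filter(fixes), fixes)

    def test_recheck_against_surviving_predecessor(self):
        # A-B slow, B-C fast; C removed, A-B untouched
        a, b, c = _at(0.0), _at(1.0), _at(21.0)
        fixes = make_fixes("b1", [0, 600, 1200], [a[0], b[0], c[0]], [a[1], b[1], c[1]])
        out = speed_filter(fixes)
        assert list(out["lat"]) == [a[0], b[0]]

    def test_no_superthreshold_pair_survives(self):
        rng = np.random.default_rng(11)
        dists = np.cumsum(rng.uniform(-30, 30, 50)).clip(0)
        pts = [_at(d) for d in dists]
        fixes = make_fixes(
            "b1", np.arange(50) * 300, [p[0] for p in pts], [p[1] for p in pts]
        )
        out = speed_filter(fixes, vmax_ms=30.0)
        lat, lon = out["lat"].to_numpy(), out["lon"].to_numpy()
        dt = out["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
        sp = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 1000.0 / dt
        assert (sp <= 30.0).all()
        # idempotence on its own output
        pd.testing.assert_frame_equal(speed_filter(out), out)


class TestSegmentation:
    def test_gap_splits(self):
        fixes = make_fixes("b1", [0, 300, 4300, 4600], [56.0] * 4, [-2.0] * 4)
        out = segment_by_gaps(fixes)
        assert list(out["segment_id"]) == [0, 0, 1, 1]

    def test_single_fix_singleton_segment(self):
        out = segment_by_gaps(make_fixes("b1", [0], [56.0], [-2.0]))
        assert list(out["segment_id"]) == [0]

    def test_exact_hour_gap_does_not_split(self):
        fixes = make_fixes("b1", [0, 3600, 7200], [56.0] * 3, [-2.0] * 3)
        assert segment_by_gaps(fixes)["segment_id"].nunique() == 1


def test_clean_report_reconciles():
    a, b = _at(5.0), _at(2000.0)
    fixes = make_fixes(
        "b1",
        [0, 0, 600, 660, 1200],
        [a[0], a[0], a[0], a[0], b[0]],
        [a[1], a[1], a[1], a[1], b[1]],
    )
    cleaned, report = clean_gps(fixes, np.random.default_rng(0), colony=COLONY)
    assert report.input_rows == 5
    assert report.input_rows - report.output_rows == report.total_removed
    assert report.removed_bbox == 1  # the 2000 km fix
    assert report.removed_duplicate_timestamp == 1
    assert report.removed_identical_consecutive >= 1
    assert "segment_id" in cleaned.columns
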