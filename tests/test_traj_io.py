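import math
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from foxmove import (
    Fix,
    Projection,
    SimWorld,
    Track,
    assign_season,
    classify_habitat,
    qc_speed_filter,
    read_telemetry,
    season_instance,
    thin_daily,
    write_telemetry,
)
from foxmove.traj_io import mean_interval_hours

UTC = timezone.utc


def fix_at(day_offset, x=0.0, y=0.0, hour=12, animal="A", habitat="land"):
    return Fix(
        animal_id=animal,
        species="red",
        timestamp=datetime(2020, 1, 1, hour, tzinfo=UTC) + timedelta(days=day_offset),
        x=x,
        y=y,
        habitat=habitat,
    )


class TestReadTelemetry:
    def test_malformed_rows_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "animal_id,species,timestamp,lon,lat\n"
            "A,red,2020-01-01T00:00:00Z,-94.0,58.0\n"
            "A,red,2020-01-02T00:00:00Z,-94.1,58.1\n"
            "A,red,2020-01-03T00:00:00Z,-94.0,\n"
            "A,red,2020-01-04T00:00:00Z,-94.2,58.0\n"
        )
        tracks, rejected = read_telemetry(p)
        assert sum(len(t) for t in tracks) == 3
        assert len(rejected) == 1
        assert rejected["reason"].iloc[0] == "missing coordinate"

    def test_unparseable_timestamp_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "animal_id,species,timestamp,x_km,y_km\n"
            "A,red,2020-01-01T00:00:00Z,0,0\n"
            "A,red,not-a-date,1,1\n"
        )
        tracks, rejected = read_telemetry(p)
        assert len(rejected) == 1
        assert rejected["reason"].iloc[0] == "unparseable timestamp"

    def test_missing_required_column_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("animal_id,timestamp,x_km,y_km\nA,2020-01-01,0,0\n")
        with pytest.raises(ValueError, match="species"):
            read_telemetry(p)

    def test_planar_input_passes_through(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "animal_id,species,timestamp,x_km,y_km\n"
            "A,red,2020-01-01T00:00:00Z,3.5,-2.25\n"
        )
        tracks, _ = read_telemetry(p)
        assert tracks[0].fixes[0].x == 3.5
        assert tracks[0].fixes[0].y == -2.25

    def test_one_degree_latitude_near_111_2_km(self):
        # geodesic oracle: a degree of latitude is ~111.2 km at 58 N
        proj = Projection(lon0=-94.0, lat0=58.0)
        x1, y1 = proj.forward(np.array([-94.0]), np.array([57.5]))
        x2, y2 = proj.forward(np.array([-94.0]), np.array([58.5]))
        d = math.hypot(x2[0] - x1[0], y2[0] - y1[0])
        assert abs(d - 111.2) / 111.2 < 0.005

    def test_roundtrip_write_read(self, tmp_path):
        track = Track("A", "red", [fix_at(i, x=float(i)) for i in range(3)])
        path = tmp_path / "out.csv"
        write_telemetry([track], path)
        back, rejected = read_telemetry(path)
        assert len(rejected) == 0
        assert back[0].xy() == pytest.approx(track.xy())


class TestThinDaily:
    def test_48_fixes_over_2_days_thin_to_2(self):
        fixes = [
            Fix("A", "red", datetime(2020, 1, 1, tzinfo=UTC) + timedelta(hours=h),
                float(h), 0.0)
            for h in range(48)
        ]
        thinned = thin_daily(Track("A", "red", fixes), seed=0, utc_offset_hours=0)
        assert len(thinned) == 2
        assert thinned.thinned

    def test_single_fix_day_always_kept(self):
        fixes = [fix_at(0, x=1.0)]
        for seed in range(20):
            t = thin_daily(Track("A", "red", fixes), seed=seed)
            assert t.fixes[0].x == 1.0

    def test_idempotent(self):
        fixes = [
            Fix("A", "red", datetime(2020, 1, 1, tzinfo=UTC) + timedelta(hours=h),
                float(h), 0.0)
            for h in range(0, 72, 3)
        ]
        once = thin_daily(Track("A", "red", fixes), seed=3)
        twice = thin_daily(once, seed=99)
        assert [f.timestamp for f in twice.fixes] == [f.timestamp for f in once.fixes]

    def test_empty_track_raises(self):
        with pytest.raises(ValueError, match="empty"):
            thin_daily(Track("A", "red", []), seed=0)

    def test_uniform_selection_frequency(self):
        # binomial oracle: each of 10 fixes picked ~1/10 of the time
        fixes = [
            Fix("A", "red", datetime(2020, 1, 1, h, tzinfo=UTC), float(h), 0.0)
            for h in range(10)
        ]
        track = Track("A", "red", fixes)
        counts = np.zeros(10)
        n_trials = 1000
        for seed in range(n_trials):
            kept = thin_daily(track, seed=seed, utc_offset_hours=0)
            counts[int(kept.fixes[0].x)] += 1
        # 99% binomial bound on each cell
        p = 0.1
        bound = 2.576 * math.sqrt(p * (1 - p) / n_trials)
        assert np.all(np.abs(counts / n_trials - p) < bound + 1e-9)

    def test_per_animal_streams_independent(self):
        fixes_a = [
            Fix("A", "red", datetime(2020, 1, 1, h, tzinfo=UTC), float(h), 0.0)
            for h in range(10)
        ]
        fixes_b = [
            Fix("B", "red", datetime(2020, 1, 1, h, tzinfo=UTC), float(h), 0.0)
            for h in range(10)
        ]
        solo = thin_daily(Track("A", "red", fixes_a), seed=5)
        # thinning B first must not change A's draw
        thin_daily(Track("B", "red", fixes_b), seed=5)
        again = thin_daily(Track("A", "red", fixes_a), seed=5)
        assert [f.x for f in solo.fixes] == [f.x for f in again.fixes]

    def test_mean_interval_24h_on_gapless_daily_track(self):
        track = Track("A", "red", [fix_at(i) for i in range(30)])
        assert mean_interval_hours(track) == pytest.approx(24.0)


class TestSeasons:
    @pytest.mark.parametrize(
        "month,day,expected",
        [(5, 14, "winter"), (5, 15, "summer"), (10, 31, "summer"), (11, 1, "winter"),
         (1, 15, "winter"), (7, 1, "summer")],
    )
    def test_boundaries(self, month, day, expected):
        assert assign_season(datetime(2020, month, day, tzinfo=UTC)) == expected

    def test_total_and_single_valued_over_a_year(self):
        d = date(2019, 1, 1)
        while d < date(2020, 1, 1):
            label = assign_season(d)  # raises if no window matches
            assert label in ("summer", "winter")
            d += timedelta(days=1)

    def test_winter_instance_keeps_starting_year(self):
        assert season_instance(datetime(2019, 12, 1, tzinfo=UTC)) == ("winter", 2019)
        assert season_instance(datetime(2020, 3, 1, tzinfo=UTC)) == ("winter", 2019)
        assert season_instance(datetime(2020, 7, 1, tzinfo=UTC)) == ("summer", 2020)


class TestHabitat:
    def test_point_on_land(self, world):
        label, implausible = classify_habitat(fix_at(0, x=-10.0, y=0.0), world)
        assert (label, implausible) == ("land", False)

    def test_sea_point_in_ice_window(self, world):
        f = Fix("A", "red", datetime(2020, 1, 15, tzinfo=UTC), 30.0, 0.0)
        label, implausible = classify_habitat(f, world)
        assert (label, implausible) == ("sea", False)

    def test_sea_point_outside_ice_window_flagged(self, world):
        f = Fix("A", "red", datetime(2020, 8, 15, tzinfo=UTC), 30.0, 0.0)
        label, implausible = classify_habitat(f, world)
        assert (label, implausible) == ("sea", True)

    def test_boundary_point_is_land(self, world):
        # coastline tie-break: exactly on the boundary resolves to land
        f = Fix("A", "red", datetime(2020, 1, 15, tzinfo=UTC), 0.0, 0.0)
        label, _ = classify_habitat(f, world)
        assert label == "land"

    def test_point_nowhere_is_unknown(self, world):
        f = Fix("A", "red", datetime(2020, 1, 15, tzinfo=UTC), 0.0, 9999.0)
        label, _ = classify_habitat(f, world)
        assert label == "unknown"


class TestSpeedFilter:
    def test_stationary_track_untouched(self):
        track = Track("A", "red", [fix_at(i, x=0.01 * i) for i in range(10)])
        kept, rejected = qc_speed_filter(track, max_kmh=50.0)
        assert len(kept) == 10 and rejected == []

    def test_teleported_fix_removed(self):
        fixes = [
            Fix("A", "red", datetime(2020, 1, 1, h, tzinfo=UTC), 0.0, 0.0)
            for h in range(5)
        ]
        fixes[2] = Fix("A", "red", datetime(2020, 1, 1, 2, tzinfo=UTC), 500.0, 0.0)
        kept, rejected = qc_speed_filter(Track("A", "red", fixes), max_kmh=50.0)
        assert len(rejected) == 1 and rejected[0].x == 500.0
        assert len(kept) == 4

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        track = Track("A", "red", [fix_at(i, *rng.normal(size=2)) for i in range(20)])
        kept, rejected = qc_speed_filter(track)
        assert rejected == [] and len(kept) == 20
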