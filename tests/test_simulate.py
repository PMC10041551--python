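import math
from datetime import date

import numpy as np
import pytest
import shapely
from shapely.geometry import Point

from foxmove import (
    CohortGroup,
    CohortSpec,
    DisperserParams,
    ResidentParams,
    SimWorld,
    estimate_ud,
    simulate_cohort,
    simulate_disperser,
    simulate_resident,
)
from foxmove.simulate import heading_sd_for_tortuosity, ou_sigma_for_area


class TestSimWorld:
    def test_overlapping_polygons_rejected(self):
        from shapely.geometry import box

        with pytest.raises(ValueError, match="overlap"):
            SimWorld(land_polygon=box(-10, -10, 10, 10), sea_polygon=box(0, -10, 20, 10))

    def test_ice_window_wraps_year(self, world):
        assert world.ice_available(date(2020, 1, 15))
        assert world.ice_available(date(2019, 12, 15))
        assert not world.ice_available(date(2020, 9, 1))


class TestSimulateResident:
    def test_rate_zero_no_ground_truth_events(self, world):
        params = ResidentParams(excursion_rate=0.0, commuting_rate=0.0)
        _, events = simulate_resident(world, params, date(2019, 6, 1), 120, seed=1)
        assert events == []

    def test_determinism(self, world):
        params = ResidentParams(excursion_rate=0.2, commuting_rate=0.1)
        t1, e1 = simulate_resident(world, params, date(2019, 6, 1), 150, seed=7)
        t2, e2 = simulate_resident(world, params, date(2019, 6, 1), 150, seed=7)
        assert t1.xy().tobytes() == t2.xy().tobytes()
        assert e1 == e2

    def test_one_fix_per_day(self, world):
        params = ResidentParams()
        track, _ = simulate_resident(world, params, date(2019, 6, 1), 90, seed=2)
        days = {f.timestamp.date() for f in track.fixes}
        assert len(days) == len(track) == 90

    def test_area_calibration_summer(self, world):
        # Monte-Carlo recovery: a-LoCoH 95% area within +-30% of target
        target = 16.0
        params = ResidentParams(
            summer_hr_area=target, excursion_rate=0.0, commuting_rate=0.0
        )
        areas = []
        for seed in range(8):
            track, _ = simulate_resident(
                world, params, date(2019, 5, 20), 160, seed=seed
            )
            areas.append(estimate_ud(track.xy(), levels=(0.95,)).area(0.95))
        assert abs(np.median(areas) / target - 1.0) < 0.30

    def test_excursions_exceed_3x_range_radius_and_return(self, world):
        params = ResidentParams(excursion_rate=0.5, commuting_rate=0.0)
        track, events = simulate_resident(world, params, date(2019, 6, 1), 150, seed=9)
        assert events, "expected planted excursions at rate 0.5/week"
        c = np.array(params.centroid)
        radius = math.sqrt(params.summer_hr_area / math.pi)
        xy = track.xy()
        for e in events:
            dur = (e.end_ts - e.start_ts).days + 1
            assert dur < 7
            seg = xy[e.start_index : e.end_index + 1]
            far = np.max(np.hypot(seg[:, 0] - c[0], seg[:, 1] - c[1]))
            assert far >= 3.0 * radius

    def test_commuting_only_in_ice_window_and_on_sea(self, world):
        params = ResidentParams(
            excursion_rate=0.0, commuting_rate=0.6, excursion_max_days=3
        )
        track, events = simulate_resident(world, params, date(2019, 9, 1), 300, seed=4)
        commutes = [e for e in events if e.event_type == "commuting"]
        assert commutes, "expected commuting bouts at rate 0.6/week in ice season"
        for e in commutes:
            for i in range(e.start_index, e.end_index + 1):
                f = track.fixes[i]
                assert world.ice_available(f.timestamp.date())
                assert f.habitat == "sea"
            assert (e.end_ts - e.start_ts).days + 1 <= 3

    def test_all_fixes_in_world(self, world):
        params = ResidentParams(excursion_rate=0.3, commuting_rate=0.3)
        track, _ = simulate_resident(world, params, date(2019, 9, 1), 250, seed=6)
        union = world.land_polygon.union(world.sea_polygon).union(world.forest_polygon)
        assert all(union.covers(Point(f.x, f.y)) for f in track.fixes)

    def test_centroid_outside_land_rejected(self, world):
        params = ResidentParams(centroid=(50.0, 0.0))  # in the sea
        with pytest.raises(ValueError, match="centroid"):
            simulate_resident(world, params, date(2019, 6, 1), 90, seed=0)

    def test_too_short_rejected(self, world):
        with pytest.raises(ValueError, match="60"):
            simulate_resident(world, ResidentParams(), date(2019, 6, 1), 30, seed=0)


class TestSimulateDisperser:
    def test_straight_line_case(self, world):
        params = DisperserParams(
            start_doy=335, bearing_deg=0.0, target_distance=100.0,
            daily_speed=10.0, tortuosity=1.0, substrate="land", settle_days=None,
        )
        track, truth = simulate_disperser(world, params, resident_prefix_days=0, seed=0)
        xy = track.xy()
        steps = np.diff(xy, axis=0)
        cumulative = np.hypot(steps[:, 0], steps[:, 1]).sum()
        straight = math.hypot(*(xy[-1] - xy[0]))
        assert cumulative == pytest.approx(100.0)
        assert cumulative / straight == pytest.approx(1.0)
        assert len(track) == 11  # origin + 10 daily steps

    def test_determinism(self, world):
        params = DisperserParams()
        t1, _ = simulate_disperser(world, params, resident_prefix_days=20, seed=3)
        t2, _ = simulate_disperser(world, params, resident_prefix_days=20, seed=3)
        assert t1.xy().tobytes() == t2.xy().tobytes()

    def test_cumulative_distance_matches_table_means(self, world):
        # planted red-fox-like truth: cumulative distance 200.80 km
        params = DisperserParams(
            start_doy=340, bearing_deg=225.0, target_distance=200.80,
            daily_speed=15.24, tortuosity=1.50, substrate="land",
        )
        cums = []
        for seed in range(20):
            track, truth = simulate_disperser(world, params, 0, seed=seed)
            start = next(e for e in truth if e.event_type == "dispersal_start")
            end = next(e for e in truth if e.event_type == "dispersal_end")
            seg = track.xy()[start.start_index : end.start_index + 1]
            d = np.diff(seg, axis=0)
            cums.append(np.hypot(d[:, 0], d[:, 1]).sum())
        mean, se = np.mean(cums), np.std(cums, ddof=1) / math.sqrt(len(cums))
        assert abs(mean - 200.80) <= max(2 * se, 1.0)

    def test_settlement_localised(self, world):
        params = DisperserParams(settle_days=10)
        track, truth = simulate_disperser(world, params, 0, seed=8)
        end = next(e for e in truth if e.event_type == "dispersal_end")
        tail = track.xy()[end.start_index :]
        spread = np.ptp(tail, axis=0)
        # settlement disc bounding box is tiny next to the dispersal path
        path_bbox = np.prod(np.ptp(track.xy(), axis=0))
        assert np.prod(spread) < 0.10 * path_bbox

    def test_ice_outside_window_rejected(self, world):
        params = DisperserParams(start_doy=220, substrate="ice")
        with pytest.raises(ValueError, match="ice window"):
            simulate_disperser(world, params, 0, seed=0)

    def test_tortuosity_heading_sd_identity(self):
        assert heading_sd_for_tortuosity(1.0) == 0.0
        sd = heading_sd_for_tortuosity(2.0)
        assert math.exp(sd * sd / 2.0) == pytest.approx(2.0)


class TestSimulateCohort:
    def test_all_residents_label_table(self):
        spec = CohortSpec(
            groups=(CohortGroup(n=10, tactic="resident"),), n_days=90
        )
        tracks, truth, events = simulate_cohort(spec, seed=1)
        assert len(tracks) == 10
        assert (truth["tactic"] == "resident").all()

    def test_substrates_by_construction(self):
        spec = CohortSpec(
            groups=(
                CohortGroup(
                    n=5, tactic="disperser", species="red",
                    disperser_params=DisperserParams(substrate="land", bearing_deg=225.0),
                ),
                CohortGroup(
                    n=5, tactic="disperser", species="arctic",
                    disperser_params=DisperserParams(
                        substrate="ice", bearing_deg=30.0, start_doy=350
                    ),
                ),
            ),
        )
        tracks, truth, _ = simulate_cohort(spec, seed=2)
        red = [t for t in tracks if t.species == "red"]
        for t in red:
            assert all(f.habitat != "sea" for f in t.fixes)

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError, match="no animals"):
            CohortSpec(groups=(CohortGroup(n=0, tactic="resident"),))

    def test_winter_fraction_recovered(self):
        spec = CohortSpec(
            groups=(
                CohortGroup(
                    n=100, tactic="disperser", resident_prefix_days=0,
                    disperser_params=DisperserParams(
                        substrate="land", target_distance=60.0
                    ),
                ),
            ),
            winter_dispersal_fraction=0.56,
        )
        _, truth, _ = simulate_cohort(spec, seed=3)
        frac = (truth["dispersal_season"] == "winter").mean()
        # binomial 95% bound around the planted fraction
        bound = 1.96 * math.sqrt(0.56 * 0.44 / 100)
        assert abs(frac - 0.56) <= bound

    def test_cohort_determinism(self):
        spec = CohortSpec(
            groups=(
                CohortGroup(n=3, tactic="resident"),
                CohortGroup(n=3, tactic="disperser"),
            ),
            resident_daily_hazard=0.002,
            disperser_daily_hazard=0.018,
        )
        t1, truth1, e1 = simulate_cohort(spec, seed=9)
        t2, truth2, e2 = simulate_cohort(spec, seed=9)
        assert truth1.equals(truth2) and e1.equals(e2)
        for a, b in zip(t1, t2):
            assert a.xy().tobytes() == b.xy().tobytes()
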