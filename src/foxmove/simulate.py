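"""Synthetic telemetry with the statistical structure the pipeline assumes.

Residents follow a discrete-daily Ornstein-Uhlenbeck walk whose stationary
cloud is calibrated so the 95% a-LoCoH isopleth recovers a target area, with
planted out-and-back excursions and (for sea-ice neighbours) commuting
bouts. Dispersers run a wrapped-normal-heading correlated walk at a fixed
daily step until a cumulative-distance target is met, then settle or die.
Only daily fixes are emitted (one per day at noon UTC) because downstream
analysis is daily; coordinates are planar km throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .traj_io import Fix, Track

#: Monte-Carlo calibrated ratio (95% a-LoCoH area) / (per-axis stationary
#: variance) for daily OU fixes (reversion 0.4/day, a = max pairwise
#: distance): ~9.4 at 120 fixes, ~10.5 at 180, ~11.2 at 194. The Gaussian
#: 95% ellipse would give 2 * pi * ln(20) ~= 18.8; the finite-sample hull
#: union runs much tighter. 10.8 centres the 120-200 fix range used by the
#: season windows; recovery is checked to +-30% in the tests.
LOCOH_AREA_PER_VARIANCE = 10.8

#: Excursion reach as a multiple of the nominal range radius sqrt(A / pi);
#: at least 3x so planted trips clear the Hampel bound decisively.
EXCURSION_REACH_FACTOR = 3.5

NOON = time(12, 0, tzinfo=timezone.utc)


def _doy_in_window(doy: int, start_doy: int, end_doy: int) -> bool:
    if start_doy <= end_doy:
        return start_doy <= doy <= end_doy
    return doy >= start_doy or doy <= end_doy


@dataclass(frozen=True)
class SimWorld:
    """Rectangular stand-in landscape: forest inland, a land strip along the
    coast, and sea (ice in season) offshore east of x = 0."""

    land_polygon: Polygon = field(default_factory=lambda: box(-200.0, -3000.0, 0.0, 3000.0))
    sea_polygon: Polygon = field(default_factory=lambda: box(0.0, -3000.0, 3000.0, 3000.0))
    forest_polygon: Polygon = field(
        default_factory=lambda: box(-3000.0, -3000.0, -200.0, 3000.0)
    )
    ice_on_doy: int = 336  # ~December 2, ice consolidated
    ice_off_doy: int = 188  # ~July 7, area free of ice

    def __post_init__(self) -> None:
        pairs = [
            (self.land_polygon, self.sea_polygon),
            (self.land_polygon, self.forest_polygon),
            (self.sea_polygon, self.forest_polygon),
        ]
        for a, b in pairs:
            if a.intersection(b).area > 1e-9:
                raise ValueError("world polygons must not overlap")
        if self.ice_on_doy == self.ice_off_doy:
            raise ValueError("ice window is empty")

    def ice_available(self, when: datetime | date) -> bool:
        return _doy_in_window(when.timetuple().tm_yday, self.ice_on_doy, self.ice_off_doy)

    def habitat_at(self, x: float, y: float) -> str:
        p = Point(x, y)
        if self.land_polygon.covers(p):
            return "land"
        if self.forest_polygon.covers(p):
            return "forest"
        if self.sea_polygon.covers(p):
            return "sea"
        return "unknown"


@dataclass(frozen=True)
class ResidentParams:
    centroid: tuple[float, float] = (-20.0, 0.0)
    summer_hr_area: float = 17.0  # km^2, both species alike in summer
    winter_hr_area: float = 34.72  # km^2, red-fox-like winter expansion
    ou_reversion: float = 0.4  # 1/day
    excursion_rate: float = 0.1  # per week
    excursion_max_days: int = 3
    commuting_rate: float = 0.0  # per week, sea-ice neighbours only

    def __post_init__(self) -> None:
        if self.summer_hr_area <= 0 or self.winter_hr_area <= 0:
            raise ValueError("home-range areas must be positive")
        if self.excursion_rate < 0 or self.commuting_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 < self.excursion_max_days < 7:
            raise ValueError("excursions must be shorter than 7 days")


@dataclass(frozen=True)
class DisperserParams:
    start_doy: int = 335  # winter-initiated by default
    bearing_deg: float = 225.0  # toward the forest, red-fox-like
    target_distance: float = 200.8  # cumulative km
    daily_speed: float = 15.24  # km/day
    tortuosity: float = 1.5  # cumulative / straight-line target
    substrate: str = "land"  # land | ice | mixed
    settle_days: int | None = 10  # None = dies at the end of travel

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")
        if self.tortuosity < 1:
            raise ValueError("tortuosity must be >= 1")
        if self.substrate not in ("land", "ice", "mixed"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.settle_days is not None and self.settle_days < 1:
            raise ValueError("settle_days must be >= 1 or None (death in transit)")


@dataclass(frozen=True)
class GroundTruthEvent:
    animal_id: str
    event_type: str  # excursion | commuting | dispersal_start | dispersal_end | death
    start_ts: datetime
    end_ts: datetime
    start_index: int
    end_index: int


def ou_sigma_for_area(area_km2: float) -> float:
    """Per-axis stationary standard deviation whose a-LoCoH 95% area is
    calibrated to ``area_km2``."""
    return math.sqrt(area_km2 / LOCOH_AREA_PER_VARIANCE)


def _season_is_winter(d: date) -> bool:
    md = (d.month, d.day)
    return md >= (11, 1) or md <= (5, 14)


def _noon(d: date) -> datetime:
    return datetime.combine(d, NOON)


def _heading_unit(bearing_deg: float) -> np.ndarray:
    rad = math.radians(bearing_deg)
    return np.array([math.sin(rad), math.cos(rad)])  # compass convention


def heading_sd_for_tortuosity(tortuosity: float) -> float:
    """Wrapped-normal heading sd (radians) giving the requested path
    tortuosity: the mean step projection onto the mean heading is
    exp(-sd^2/2), so cumulative/straight ~= exp(sd^2/2)."""
    return math.sqrt(2.0 * math.log(tortuosity))


def simulate_resident(
    world: SimWorld,
    params: ResidentParams,
    start_date: date,
    n_days: int,
    seed: int,
    animal_id: str = "R0",
    species: str = "red",
) -> tuple[Track, list[GroundTruthEvent]]:
    """Daily OU resident with planted excursion and commuting bouts.

    Excursion bouts reach ``EXCURSION_REACH_FACTOR`` times the nominal range
    radius and return; commuting bouts target the sea polygon and occur only
    while ice is available. Bout days and geometry are recorded as ground
    truth. Identical seed, identical track.
    """
    if n_days < 60:
        raise ValueError("need at least 60 days for a meaningful resident track")
    if not world.land_polygon.covers(Point(*params.centroid)):
        raise ValueError("resident centroid must lie inside the land polygon")

    rng = np.random.default_rng(seed)
    c = np.array(params.centroid, dtype=float)
    phi = math.exp(-params.ou_reversion)

    days = [start_date + timedelta(days=i) for i in range(n_days)]
    winter = np.array([_season_is_winter(d) for d in days])
    sigma = np.where(
        winter,
        ou_sigma_for_area(params.winter_hr_area),
        ou_sigma_for_area(params.summer_hr_area),
    )

    # choose bout start days up front so the OU stream is unaffected by rate
    p_exc = params.excursion_rate / 7.0
    p_com = params.commuting_rate / 7.0
    exc_draw = rng.random(n_days)
    dur_draw = rng.integers(1, params.excursion_max_days + 1, size=n_days)
    com_dur_draw = rng.integers(1, min(3, params.excursion_max_days) + 1, size=n_days)
    bearing_draw = rng.uniform(90.0, 270.0, size=n_days)  # away from the coast
    offshore_draw = rng.uniform(0.2, 0.8, size=n_days)

    bouts: list[tuple[int, int, str, float]] = []  # (start, duration, kind, bearing)
    occupied = np.zeros(n_days, dtype=bool)
    for i in range(1, n_days - 7):  # leave room to return before track end
        if occupied[max(0, i - 1) : i + 8].any():
            continue
        if exc_draw[i] < p_exc:
            d = int(dur_draw[i])
            bouts.append((i, d, "excursion", float(bearing_draw[i])))
            occupied[i : i + d + 1] = True
        elif p_com > 0 and exc_draw[i] < p_exc + p_com and world.ice_available(days[i]):
            d = int(com_dur_draw[i])
            if all(world.ice_available(days[i + j]) for j in range(d)):
                bouts.append((i, d, "commuting", float(offshore_draw[i])))
                occupied[i : i + d + 1] = True
    bout_days = {}
    for start, dur, kind, extra in bouts:
        for j in range(dur):
            bout_days[start + j] = (start, dur, kind, extra, j)

    xy = np.empty((n_days, 2))
    state = c + rng.normal(0.0, sigma[0], size=2)
    noise = rng.normal(size=(n_days, 2))
    for i in range(n_days):
        if i > 0:
            step_sd = sigma[i] * math.sqrt(1.0 - phi * phi)
            state = c + phi * (state - c) + step_sd * noise[i]
        if i in bout_days:
            start, dur, kind, extra, j = bout_days[i]
            radius = math.sqrt(
                (params.winter_hr_area if winter[i] else params.summer_hr_area) / math.pi
            )
            reach = EXCURSION_REACH_FACTOR * radius
            # triangular out-and-back profile peaking mid-bout
            frac = (j + 1) / (dur + 1)
            amp = reach * (1.0 - abs(2.0 * frac - 1.0)) + reach * 0.5
            if kind == "excursion":
                pos = c + amp * _heading_unit(extra)
                if not world.land_polygon.covers(Point(*pos)) and not (
                    world.forest_polygon.covers(Point(*pos))
                ):
                    pos = c + amp * _heading_unit(200.0)
            else:
                # head offshore: east of the coast at x = 0
                depth = max(amp, abs(c[0]) + 2.0)
                pos = np.array([c[0] + depth, c[1] + (extra - 0.5) * radius])
            xy[i] = pos
        else:
            xy[i] = state

    fixes = [
        Fix(
            animal_id=animal_id,
            species=species,
            timestamp=_noon(days[i]),
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            habitat=world.habitat_at(float(xy[i, 0]), float(xy[i, 1])),
        )
        for i in range(n_days)
    ]
    events = [
        GroundTruthEvent(
            animal_id=animal_id,
            event_type=kind,
            start_ts=_noon(days[start]),
            end_ts=_noon(days[start + dur - 1]),
            start_index=start,
            end_index=start + dur - 1,
        )
        for start, dur, kind, _ in bouts
    ]
    return Track(animal_id=animal_id, species=species, fixes=fixes, thinned=True), events


def simulate_disperser(
    world: SimWorld,
    params: DisperserParams,
    resident_prefix_days: int = 0,
    seed: int = 0,
    animal_id: str = "D0",
    species: str = "arctic",
    start_year: int = 2019,
    resident_params: ResidentParams | None = None,
) -> tuple[Track, list[GroundTruthEvent]]:
    """Correlated-walk dispersal, optionally preceded by a resident prefix.

    The walk takes steps of exactly ``daily_speed`` km with wrapped-normal
    heading noise tuned to ``tortuosity``, until the cumulative path length
    reaches ``target_distance``; then ``settle_days`` of localized movement
    on land, or truncation when ``settle_days`` is None (death in transit).
    Ground-truth start/end indices are recorded.
    """
    if resident_prefix_days < 0:
        raise ValueError("resident_prefix_days must be >= 0")
    rng = np.random.default_rng(seed)
    rp = resident_params or ResidentParams(excursion_rate=0.0)

    start = date(start_year, 1, 1) + timedelta(days=params.start_doy - 1)
    if params.substrate == "ice" and not _doy_in_window(
        params.start_doy, world.ice_on_doy, world.ice_off_doy
    ):
        raise ValueError("substrate=ice requested outside the ice window")

    fixes: list[Fix] = []
    events: list[GroundTruthEvent] = []
    origin = np.array(rp.centroid, dtype=float)

    day = start - timedelta(days=resident_prefix_days)
    if resident_prefix_days > 0:
        sigma = ou_sigma_for_area(
            rp.winter_hr_area if _season_is_winter(start) else rp.summer_hr_area
        )
        phi = math.exp(-rp.ou_reversion)
        state = origin + rng.normal(0.0, sigma, size=2)
        for i in range(resident_prefix_days):
            if i > 0:
                state = origin + phi * (state - origin) + sigma * math.sqrt(
                    1 - phi * phi
                ) * rng.normal(size=2)
            fixes.append(
                _make_fix(animal_id, species, day, state, world)
            )
            day += timedelta(days=1)
        pos = np.array([fixes[-1].x, fixes[-1].y])
    else:
        pos = origin.copy()
        fixes.append(_make_fix(animal_id, species, day, pos, world))
        day += timedelta(days=1)

    start_index = len(fixes) - 1
    sd = heading_sd_for_tortuosity(params.tortuosity)
    cumulative = 0.0
    while cumulative < params.target_distance - 1e-9:
        heading = (
            params.bearing_deg + math.degrees(rng.normal(0.0, sd))
            if sd > 0
            else params.bearing_deg
        )
        # partial final step so the planted cumulative distance is exact
        step_len = min(params.daily_speed, params.target_distance - cumulative)
        pos = _confine(pos + step_len * _heading_unit(heading), world, params.substrate)
        cumulative += step_len
        fixes.append(_make_fix(animal_id, species, day, pos, world))
        day += timedelta(days=1)
    travel_end = len(fixes) - 1

    if params.settle_days is None:
        end_index = travel_end
        end_reason = "death"
    else:
        if not world.land_polygon.covers(Point(*pos)) and not world.forest_polygon.covers(
            Point(*pos)
        ):
            # settlement happens on land: walk west until ashore
            while not (
                world.land_polygon.covers(Point(*pos))
                or world.forest_polygon.covers(Point(*pos))
            ):
                pos = pos + np.array([-params.daily_speed, 0.0])
                fixes.append(_make_fix(animal_id, species, day, pos, world))
                day += timedelta(days=1)
        anchor = pos.copy()
        for _ in range(params.settle_days):
            jitter = rng.normal(0.0, 0.3, size=2)
            fixes.append(_make_fix(animal_id, species, day, anchor + jitter, world))
            day += timedelta(days=1)
        end_index = len(fixes) - 1 - params.settle_days + 1
        end_reason = "settled"

    events.append(
        GroundTruthEvent(
            animal_id=animal_id,
            event_type="dispersal_start",
            start_ts=fixes[start_index].timestamp,
            end_ts=fixes[start_index].timestamp,
            start_index=start_index,
            end_index=start_index,
        )
    )
    events.append(
        GroundTruthEvent(
            animal_id=animal_id,
            event_type="dispersal_end" if end_reason == "settled" else "death",
            start_ts=fixes[end_index].timestamp,
            end_ts=fixes[end_index].timestamp,
            start_index=end_index,
            end_index=end_index,
        )
    )
    return Track(animal_id=animal_id, species=species, fixes=fixes, thinned=True), events


def _make_fix(animal_id: str, species: str, d: date, pos: np.ndarray, world: SimWorld) -> Fix:
    return Fix(
        animal_id=animal_id,
        species=species,
        timestamp=_noon(d),
        x=float(pos[0]),
        y=float(pos[1]),
        habitat=world.habitat_at(float(pos[0]), float(pos[1])),
    )


def _confine(pos: np.ndarray, world: SimWorld, substrate: str) -> np.ndarray:
    """Keep dispersal positions on the requested substrate side of the coast
    (x = 0) and inside the world bounds."""
    x, y = pos
    if substrate == "ice":
        x = max(x, 1.0)
    elif substrate == "land":
        x = min(x, -0.5)
    minx, miny, maxx, maxy = (
        world.forest_polygon.bounds[0],
        world.forest_polygon.bounds[1],
        world.sea_polygon.bounds[2],
        world.sea_polygon.bounds[3],
    )
    return np.array([np.clip(x, minx + 1, maxx - 1), np.clip(y, miny + 1, maxy - 1)])


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortGroup:
    n: int
    tactic: str  # resident | disperser
    species: str = "red"
    resident_params: ResidentParams = field(default_factory=ResidentParams)
    disperser_params: DisperserParams = field(default_factory=DisperserParams)
    resident_prefix_days: int = 40


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[CohortGroup, ...]
    start_date: date = date(2019, 5, 20)
    n_days: int = 240
    resident_daily_hazard: float = 0.0
    disperser_daily_hazard: float = 0.0
    winter_dispersal_fraction: float = 11.0 / 12.0

    def __post_init__(self) -> None:
        if not self.groups or all(g.n == 0 for g in self.groups):
            raise ValueError("cohort config names no animals")


#: Winter day-of-year pool for sampled dispersal starts (Nov 14 - May 10
#: band observed for winter-initiated events); summer starts fall mid-season.
_WINTER_START_DOYS = tuple(range(318, 366)) + tuple(range(1, 131))
_SUMMER_START_DOYS = tuple(range(166, 259))


def simulate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[Track], pd.DataFrame, pd.DataFrame]:
    """Simulate a mixed cohort with per-animal ground truth.

    Returns ``(tracks, truth, events)``: ``truth`` has one row per animal
    (animal_id, species, tactic, death_date, dispersal start season),
    ``events`` one row per planted bout/dispersal marker. Dispersal start
    days are drawn from winter with probability ``winter_dispersal_fraction``.
    Deaths follow tactic-specific exponential daily hazards and truncate the
    track.
    """
    rng = np.random.default_rng(seed)
    tracks: list[Track] = []
    truth_rows = []
    event_rows = []
    idx = 0
    for group in spec.groups:
        for _ in range(group.n):
            animal_id = f"{group.species[:1].upper()}{group.tactic[:1]}{idx:03d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if group.tactic == "resident":
                track, events = simulate_resident(
                    SimWorld(),
                    group.resident_params,
                    spec.start_date,
                    spec.n_days,
                    seed=sub_seed,
                    animal_id=animal_id,
                    species=group.species,
                )
                hazard = spec.resident_daily_hazard
                start_season = ""
            elif group.tactic == "disperser":
                in_winter = rng.random() < spec.winter_dispersal_fraction
                pool = _WINTER_START_DOYS if in_winter else _SUMMER_START_DOYS
                doy = int(pool[rng.integers(0, len(pool))])
                dp = DisperserParams(
                    start_doy=doy,
                    bearing_deg=group.disperser_params.bearing_deg,
                    target_distance=group.disperser_params.target_distance,
                    daily_speed=group.disperser_params.daily_speed,
                    tortuosity=group.disperser_params.tortuosity,
                    substrate=group.disperser_params.substrate,
                    settle_days=group.disperser_params.settle_days,
                )
                track, events = simulate_disperser(
                    SimWorld(),
                    dp,
                    resident_prefix_days=group.resident_prefix_days,
                    seed=sub_seed,
                    animal_id=animal_id,
                    species=group.species,
                )
                hazard = spec.disperser_daily_hazard
                start_season = "winter" if in_winter else "summer"
            else:
                raise ValueError(f"unknown tactic {group.tactic!r}")

            death_date = None
            if hazard > 0:
                u = rng.random()
                t_death = -math.log(u) / hazard
                if t_death < len(track):
                    cut = max(int(math.ceil(t_death)), 2)
                    death_date = track.fixes[min(cut, len(track)) - 1].timestamp.date()
                    track = Track(
                        animal_id=track.animal_id,
                        species=track.species,
                        fixes=track.fixes[: min(cut, len(track))],
                        thinned=True,
                    )
                    event_rows.append(
                        {
                            "animal_id": animal_id,
                            "event_type": "death",
                            "start_ts": _noon(death_date),
                            "end_ts": _noon(death_date),
                        }
                    )

            tracks.append(track)
            truth_rows.append(
                {
                    "animal_id": animal_id,
                    "species": group.species,
                    "tactic": group.tactic,
                    "death_date": death_date,
                    "dispersal_season": start_season,
                }
            )
            for e in events:
                if death_date is not None and e.start_ts.date() > death_date:
                    continue
                event_rows.append(
                    {
                        "animal_id": animal_id,
                        "event_type": e.event_type,
                        "start_ts": e.start_ts,
                        "end_ts": e.end_ts,
                    }
                )
            idx += 1

    truth = pd.DataFrame(truth_rows)
    events_df = pd.DataFrame(
        event_rows, columns=["animal_id", "event_type", "start_ts", "end_ts"]
    )
    return tracks, truth, events_df


def simulate_winter_survival(
    n_residents: int,
    n_dispersers: int,
    resident_daily_hazard: float,
    hazard_ratio: float,
    winter_year: int,
    seed: int,
) -> tuple[list, dict[str, date | None]]:
    """Sample one winter of tactic-specific exponential mortality.

    Death times run from Nov 1 of ``winter_year``; animals alive at May 14
    are censored downstream. Returns ``(labels, death_dates)`` ready for the
    survival-table builder. The planted effect is the disperser/resident
    hazard ratio.
    """
    from .tactics import TacticLabel, winter_window

    rng = np.random.default_rng(seed)
    start, end = winter_window(winter_year)
    window_days = (end - start).days
    labels, deaths = [], {}
    for i in range(n_residents + n_dispersers):
        tactic = "resident" if i < n_residents else "disperser"
        hazard = resident_daily_hazard * (1.0 if tactic == "resident" else hazard_ratio)
        animal_id = f"S{i:03d}"
        labels.append(TacticLabel(animal_id, "winter", winter_year, tactic))
        t = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
        deaths[animal_id] = (
            start + timedelta(days=int(math.ceil(t))) if t <= window_days else None
        )
    return labels, deaths
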