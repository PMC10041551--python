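"""Movement-tactic classification and dispersal segmentation.

A season's track is resident when it holds enough fixes, no dispersal is
segmented, and the centroid of its first half sits close to the centroid of
its second half (nondirectional movement); a season with a segmented
dispersal is a disperser; anything else is insufficient. Dispersal metrics
follow the track-parameter definitions: cumulative daily path length,
straight start-to-end distance, their ratio, compass bearing of the
start-to-end vector, and mean daily speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from .homerange import UtilizationDistribution, estimate_ud
from .traj_io import Track

MIN_RESIDENT_FIXES = 38  # asymptote threshold for usable home ranges

SETTLE_MIN_DAYS = 8  # settlement means >7 consecutive days in one area
SETTLE_RADIUS_KM = 5.0
SETTLE_MAX_GAP_DAYS = 1
MIN_NET_DISPLACEMENT_KM = 20.0
PREFIX_RESIDENT_RADIUS_KM = 8.0
SUBSTRATE_MAJORITY = 0.70


@dataclass(frozen=True)
class TacticLabel:
    animal_id: str
    season: str
    year: int
    tactic: str  # resident | disperser | insufficient | capture-season-excluded


@dataclass
class DispersalEvent:
    animal_id: str
    start_index: int
    end_index: int  # inclusive
    start_time: datetime
    end_time: datetime
    end_reason: str  # settled | died | track_end
    duration_days: float
    cumulative_km: float
    straight_km: float
    csld_ratio: float
    bearing_deg: float
    mean_daily_speed_kmd: float
    main_substrate: str  # land | ice | mixed


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    winter_year: int
    tactic: str
    time_days: int
    event: int  # 1 = death, 0 = censored


def _bearing_deg(dx: float, dy: float) -> float:
    """Compass bearing of (east, north) displacement, degrees from due North."""
    return float(math.degrees(math.atan2(dx, dy)) % 360.0)


def _cumulative_km(xy: np.ndarray) -> float:
    steps = np.diff(xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _is_landish(habitat: str) -> bool:
    # settlement must be on solid ground; forest counts, sea ice does not
    return habitat in ("land", "forest", "unknown")


def _find_settlement(
    xy: np.ndarray,
    times: Sequence[datetime],
    habitats: Sequence[str],
    start: int,
    r_settle: float,
    min_days: int,
    max_gap_days: int,
    exclude_center: np.ndarray | None = None,
    exclude_radius: float = 0.0,
) -> int | None:
    """First index after ``start`` opening a >=min_days run of fixes on land
    that all stay within ``r_settle`` of their running centroid.

    A window whose centroid still sits within ``exclude_radius`` of
    ``exclude_center`` is not a *new* ranging area (it is the old range) and
    is skipped.
    """
    n = len(xy)
    for e in range(start + 1, n):
        if not _is_landish(habitats[e]):
            continue
        centroid = xy[e].astype(float).copy()
        count = 1
        last = e
        for j in range(e + 1, n):
            gap = (times[j].date() - times[last].date()).days - 1
            if gap > max_gap_days:
                break
            trial = (centroid * count + xy[j]) / (count + 1)
            window = xy[e : j + 1]
            if np.max(np.hypot(window[:, 0] - trial[0], window[:, 1] - trial[1])) > r_settle:
                break
            if not _is_landish(habitats[j]):
                break
            centroid, count, last = trial, count + 1, j
        span = (times[last].date() - times[e].date()).days + 1
        if span >= min_days:
            if exclude_center is not None and (
                float(np.hypot(*(centroid - exclude_center))) <= exclude_radius
            ):
                continue
            return e
    return None


def _departure_from_ud(
    xy: np.ndarray, prior_ud: UtilizationDistribution
) -> tuple[int | None, float, np.ndarray]:
    """Last fix inside the prior 95% isopleth never followed by a return.

    Returns (start index or None if the animal never leaves for good, scale
    of the prior range as a gate for what counts as leaving, range centre)."""
    poly = prior_ud.polygon(0.95)
    center = np.array(prior_ud.centroid, dtype=float)
    inside = shapely.covers(poly, shapely.points(xy))
    diameter = 2.0 * math.sqrt(max(prior_ud.area(0.95), 1e-12) / math.pi)
    if inside[-1]:
        return None, diameter, center
    if not inside.any():
        return 0, diameter, center
    start = int(np.max(np.nonzero(inside)[0]))
    if start == len(xy) - 1:
        return None, diameter, center
    return start, diameter, center


#: The early-fix anchor disc underestimates the full range, so membership
#: tests widen it by this factor.
_ANCHOR_MARGIN = 2.0


def _departure_self_anchored(
    xy: np.ndarray, prefix_radius_km: float
) -> tuple[int | None, float, np.ndarray]:
    """Departure without a prior UD: anchor on the early fixes; if they are
    circumscribed, the start is the last fix within the (widened) anchor
    disc never followed by a return, otherwise the animal was already
    travelling and the start is the first fix."""
    n = len(xy)
    m = max(3, min(30, n // 4))
    anchor = np.median(xy[:m], axis=0)
    d = np.hypot(xy[:, 0] - anchor[0], xy[:, 1] - anchor[1])
    r_anchor = float(d[:m].max())
    if r_anchor > prefix_radius_km:
        return 0, r_anchor, anchor  # captured while already travelling
    disc = max(_ANCHOR_MARGIN * r_anchor, 1e-9)
    inside = d <= disc
    if inside[-1] or not inside.any():
        return None, disc, anchor
    start = int(np.max(np.nonzero(inside)[0]))
    if start == n - 1:
        return None, disc, anchor
    return start, disc, anchor


def segment_dispersal(
    track: Track,
    prior_ud: UtilizationDistribution | None = None,
    *,
    r_settle: float = SETTLE_RADIUS_KM,
    settle_min_days: int = SETTLE_MIN_DAYS,
    settle_max_gap_days: int = SETTLE_MAX_GAP_DAYS,
    min_net_km: float = MIN_NET_DISPLACEMENT_KM,
    prefix_radius_km: float = PREFIX_RESIDENT_RADIUS_KM,
    died: bool = False,
) -> DispersalEvent | None:
    """Segment a long-range movement out of a thinned track, if present.

    Start: the last fix inside the prior range (95% isopleth if supplied,
    otherwise a disc around the early fixes) that is never followed by a
    return; the first fix when the animal shows no circumscribed prefix.
    End: the first fix of the earliest settlement window (>= settle_min_days
    consecutive days on land within a disc of radius ``r_settle``), else the
    last fix with reason died/track_end. Departures whose net displacement
    stays under ``min_net_km`` are not dispersals.
    """
    xy = track.xy()
    n = len(xy)
    if n < 2:
        return None
    times = track.times()
    habitats = track.habitats()

    if prior_ud is not None:
        start, scale, center = _departure_from_ud(xy, prior_ud)
        gate = max(min_net_km, 2.0 * scale)
    else:
        start, scale, center = _departure_self_anchored(xy, prefix_radius_km)
        gate = max(min_net_km, 3.0 * scale)
    if start is None:
        return None

    end = _find_settlement(
        xy,
        times,
        habitats,
        start,
        r_settle,
        settle_min_days,
        settle_max_gap_days,
        exclude_center=center,
        exclude_radius=max(gate, scale + r_settle),
    )
    if end is not None:
        reason = "settled"
    else:
        end = n - 1
        reason = "died" if died else "track_end"
    if end <= start:
        return None

    seg = xy[start : end + 1]
    net = float(np.hypot(*(seg[-1] - seg[0])))
    if net < gate:
        return None

    cumulative = _cumulative_km(seg)
    duration = (times[end] - times[start]).total_seconds() / 86400.0
    dx, dy = seg[-1] - seg[0]
    seg_hab = habitats[start : end + 1]
    n_seg = len(seg_hab)
    land_frac = sum(1 for h in seg_hab if h != "sea") / n_seg
    ice_frac = sum(1 for h in seg_hab if h == "sea") / n_seg
    if land_frac >= SUBSTRATE_MAJORITY:
        substrate = "land"
    elif ice_frac >= SUBSTRATE_MAJORITY:
        substrate = "ice"
    else:
        substrate = "mixed"

    return DispersalEvent(
        animal_id=track.animal_id,
        start_index=start,
        end_index=end,
        start_time=times[start],
        end_time=times[end],
        end_reason=reason,
        duration_days=duration,
        cumulative_km=cumulative,
        straight_km=net,
        csld_ratio=cumulative / net,
        bearing_deg=_bearing_deg(dx, dy),
        mean_daily_speed_kmd=cumulative / duration if duration > 0 else float("nan"),
        main_substrate=substrate,
    )


def classify_tactic(
    track: Track,
    season: str,
    year: int,
    prior_ud: UtilizationDistribution | None = None,
    min_fixes: int = MIN_RESIDENT_FIXES,
    ud_engine: Callable[[np.ndarray], UtilizationDistribution] = estimate_ud,
    **segment_kwargs,
) -> tuple[TacticLabel, DispersalEvent | None]:
    """Label one animal-season as resident, disperser, or insufficient.

    Resident requires at least ``min_fixes`` fixes, no segmented dispersal,
    and a between-halves centroid displacement smaller than the 95% range
    diameter. No randomness: the label is a pure function of the track.
    """
    event = segment_dispersal(track, prior_ud, **segment_kwargs)
    if event is not None:
        return TacticLabel(track.animal_id, season, year, "disperser"), event

    n = len(track)
    if n < min_fixes:
        return TacticLabel(track.animal_id, season, year, "insufficient"), None

    xy = track.xy()
    half = n // 2
    c1, c2 = xy[:half].mean(axis=0), xy[half:].mean(axis=0)
    net = float(np.hypot(*(c2 - c1)))
    ud = ud_engine(xy)
    diameter = 2.0 * math.sqrt(max(ud.area(0.95), 1e-12) / math.pi)
    if net < diameter:
        return TacticLabel(track.animal_id, season, year, "resident"), None
    return TacticLabel(track.animal_id, season, year, "insufficient"), None


_METRICS = {
    "duration_days": "duration_days",
    "cumulative_km": "cumulative_km",
    "csld_ratio": "csld_ratio",
    "mean_daily_speed_kmd": "mean_daily_speed_kmd",
}


def dispersal_summary(events_by_group: dict[str, Sequence[DispersalEvent]]) -> pd.DataFrame:
    """Per-group summary (mean, se, median, min, max, n) of each track metric."""
    rows = []
    for group, events in events_by_group.items():
        if not events:
            raise ValueError(f"no dispersal events for group {group!r}")
        for label, attr in _METRICS.items():
            vals = np.array([getattr(e, attr) for e in events], dtype=float)
            n = len(vals)
            rows.append(
                {
                    "group": group,
                    "parameter": label,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan,
                    "median": float(np.median(vals)),
                    "min": vals.min(),
                    "max": vals.max(),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def winter_window(winter_year: int, start=(11, 1), end=(5, 14)) -> tuple[date, date]:
    return date(winter_year, *start), date(winter_year + 1, *end)


def build_survival_table(
    labels: Iterable[TacticLabel],
    death_dates: dict[str, date | None],
    winter_start: tuple[int, int] = (11, 1),
    winter_end: tuple[int, int] = (5, 14),
) -> pd.DataFrame:
    """Right-censored time-to-event table for winter survival.

    Time runs in days from the start of each winter (Nov 1). A death inside
    the window is an event at (death - Nov 1) days; survival to the window
    end is censored there. Only winter labels contribute rows. The fit
    itself is left to external survival packages.
    """
    records = []
    for lab in labels:
        if lab.season != "winter" or lab.tactic in (
            "insufficient",
            "capture-season-excluded",
        ):
            continue
        start, end = winter_window(lab.year, winter_start, winter_end)
        death = death_dates.get(lab.animal_id)
        if death is not None and death < start:
            raise ValueError(
                f"{lab.animal_id}: death {death} precedes winter start {start}"
            )
        if death is not None and death <= end:
            time_days, event = (death - start).days, 1
        else:
            time_days, event = (end - start).days, 0
        records.append(
            SurvivalRecord(lab.animal_id, lab.year, lab.tactic, time_days, event)
        )
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "winter_year": r.winter_year,
                "tactic": r.tactic,
                "time_days": r.time_days,
                "event": r.event,
            }
            for r in records
        ]
    )
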