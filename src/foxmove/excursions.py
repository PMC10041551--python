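"""Extraterritorial excursion detection for resident animals.

Trips are maximal runs of consecutive fixes outside the 95% isopleth that
return to the range. A trip is an excursion when its farthest fix lies beyond
a one-sided Hampel bound (median + k * MAD of transformed centroid
distances, k = 3) and it lasts under 7 days; excursions touching sea ice are
commuting trips, the rest of the flagged trips stay excursions, and
non-outlier trips are border movements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import shapely

from .homerange import UtilizationDistribution
from .traj_io import Track

logger = logging.getLogger(__name__)

MAX_EXCURSION_DAYS = 7.0

#: Tukey ladder-of-powers exponents tried when choosing the distance
#: transform (0 stands for log).
TUKEY_LADDER = (-1.0, -0.5, 0.0, 1.0 / 3.0, 0.5, 1.0)


@dataclass(frozen=True)
class HampelBound:
    exponent: float  # Tukey ladder exponent; 0 = log, 1 = identity
    median: float  # on the transformed scale
    mad: float  # on the transformed scale
    k: float
    upper: float  # transformed-scale bound
    raw_threshold: float  # back-transformed bound on the km scale

    def exceeds(self, distance_km: float) -> bool:
        return distance_km > self.raw_threshold


@dataclass
class Trip:
    start_index: int
    end_index: int  # inclusive
    start_time: datetime
    end_time: datetime
    farthest_index: int
    farthest_distance_km: float
    duration_days: float
    habitats: tuple[str, ...]


@dataclass
class ExcursionEvent:
    animal_id: str
    season: str
    trip: Trip
    is_outlier: bool
    kind: str  # excursion | commuting | border-movement


def centroid_distances(
    points: np.ndarray, ud: UtilizationDistribution
) -> np.ndarray:
    """Euclidean distance (km) from each fix to the 95% range centroid."""
    if ud is None:
        raise ValueError("a resident utilization distribution is required")
    points = np.asarray(points, dtype=float)
    cx, cy = ud.centroid
    return np.hypot(points[:, 0] - cx, points[:, 1] - cy)


def _tukey(x: np.ndarray, p: float) -> np.ndarray:
    # monotone-increasing form of the ladder so one-sided bounds carry over
    if p == 0.0:
        return np.log(x)
    if p < 0:
        return -np.power(x, p)
    return np.power(x, p)


def _tukey_inverse(y: float, p: float) -> float:
    if p == 0.0:
        return float(np.exp(y))
    if p < 0:
        if y >= 0:
            return float("inf")
        return float((-y) ** (1.0 / p))
    if y <= 0:
        return 0.0
    return float(y ** (1.0 / p))


def _normality_score(z: np.ndarray) -> float:
    """Correlation of sorted values with normal quantiles (probability-plot
    correlation); higher is straighter."""
    from scipy import stats

    z = np.sort(z)
    n = len(z)
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    if np.ptp(z) == 0:
        return -np.inf
    return float(np.corrcoef(z, q)[0, 1])


def choose_transform(distances: np.ndarray, exponent: float | None = None) -> float:
    """Pick the Tukey ladder exponent making the distances most normal.

    The source method names "Tukey-transformed distance" without an exponent;
    by default the exponent is chosen from the classic ladder by maximising
    normal-quantile correlation, and it can be pinned via ``exponent``.
    Exponents undefined for the data (log or negative powers with zeros) are
    skipped.
    """
    if exponent is not None:
        return exponent
    distances = np.asarray(distances, dtype=float)
    best_p, best_score = 1.0, -np.inf
    for p in TUKEY_LADDER:
        if p <= 0 and np.any(distances <= 0):
            continue
        score = _normality_score(_tukey(distances, p))
        if score > best_score:
            best_p, best_score = p, score
    return best_p


def hampel_bound(
    distances: np.ndarray,
    exponent: float | None = None,
    k: float = 3.0,
    mad_scale: float = 1.0,
) -> HampelBound:
    """One-sided Hampel bound on centroid distances.

    The bound is median + k * MAD computed on the transformed scale and
    mapped back through the inverse transform. MAD is the raw median
    absolute deviation; set ``mad_scale=1.4826`` for the normal-consistent
    version. If every distance is identical and the chosen transform is
    undefined at the data, the identity transform is used instead (logged).
    """
    distances = np.asarray(distances, dtype=float)
    if len(distances) < 5:
        raise ValueError("need at least 5 distances for a robust bound")
    p = choose_transform(distances, exponent)
    if p <= 0 and np.any(distances <= 0):
        logger.warning(
            "transform exponent %s undefined for non-positive distances; "
            "falling back to identity",
            p,
        )
        p = 1.0
    z = _tukey(distances, p)
    med = float(np.median(z))
    mad = float(np.median(np.abs(z - med))) * mad_scale
    upper = med + k * mad
    return HampelBound(
        exponent=p,
        median=med,
        mad=mad,
        k=k,
        upper=upper,
        raw_threshold=_tukey_inverse(upper, p),
    )


def detect_trips(track: Track, ud: UtilizationDistribution) -> list[Trip]:
    """Maximal runs of consecutive out-of-range fixes bracketed by in-range
    fixes. Runs still open at track end cannot demonstrate a return and are
    discarded."""
    points = track.xy()
    poly = ud.polygon(0.95)
    inside = shapely.covers(poly, shapely.points(points))
    dists = centroid_distances(points, ud)
    times = track.times()
    habs = track.habitats()

    trips: list[Trip] = []
    i, n = 0, len(points)
    while i < n:
        if inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not inside[j + 1]:
            j += 1
        returned = j + 1 < n  # an in-range fix follows
        preceded = i > 0
        if returned and preceded:
            far_rel = int(np.argmax(dists[i : j + 1]))
            far = i + far_rel
            trips.append(
                Trip(
                    start_index=i,
                    end_index=j,
                    start_time=times[i],
                    end_time=times[j],
                    farthest_index=far,
                    farthest_distance_km=float(dists[far]),
                    duration_days=(times[j] - times[i]).total_seconds() / 86400.0
                    + 1.0,
                    habitats=tuple(habs[i : j + 1]),
                )
            )
        i = j + 1
    return trips


def classify_excursions(
    trips: Sequence[Trip],
    bound: HampelBound,
    animal_id: str = "",
    season: str = "",
) -> list[ExcursionEvent]:
    """Label each trip.

    Outlier test applies to the trip's farthest fix only. An outlier trip
    under 7 days is an excursion; if any of its fixes are on sea ice it is a
    commuting trip. Everything else is border movement.
    """
    events = []
    for trip in trips:
        outlier = bound.exceeds(trip.farthest_distance_km)
        if outlier and trip.duration_days < MAX_EXCURSION_DAYS:
            kind = "commuting" if "sea" in trip.habitats else "excursion"
        else:
            kind = "border-movement"
        events.append(
            ExcursionEvent(
                animal_id=animal_id,
                season=season,
                trip=trip,
                is_outlier=outlier,
                kind=kind,
            )
        )
    return events


def weekly_frequency(n_events: int, span_days: float) -> float:
    """Events per week over a tracking span (raw counts are not comparable
    across animals tracked for different lengths of time)."""
    if span_days <= 0:
        raise ValueError("tracking span must be positive")
    return n_events / (span_days / 7.0)
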