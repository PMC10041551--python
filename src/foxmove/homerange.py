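"""Local convex hull (LoCoH) utilization distributions.

The adaptive method grows each point's neighbourhood in order of Euclidean
distance until the cumulative neighbour distance reaches ``a``; the local
hulls are then unioned in ascending-area order (a density proxy) until the
union covers the requested fraction of fixes, yielding nested isopleth
polygons. The time-scaling parameter ``s`` is fixed at 0, so ordering is by
plain Euclidean distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

DEFAULT_LEVELS = (0.50, 0.95)


@dataclass(frozen=True)
class LocohParams:
    """Hull construction parameters.

    method 'a': cumulative-distance radius ``a`` (km);
    method 'k': ``k`` nearest neighbours; method 'r': fixed radius ``r`` (km).
    """

    method: str = "a"
    a: float | None = None
    k: int | None = None
    r: float | None = None
    s: float = 0.0
    isopleth_levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if self.method not in ("a", "k", "r"):
            raise ValueError(f"unknown LoCoH method {self.method!r}")
        if self.s != 0.0:
            raise ValueError("time-scaled distance (s > 0) is unsupported; s must be 0")
        value = {"a": self.a, "k": self.k, "r": self.r}[self.method]
        if value is None or value <= 0:
            raise ValueError(f"method {self.method!r} requires a positive parameter")
        for lvl in self.isopleth_levels:
            if not 0.0 < lvl <= 1.0:
                raise ValueError(f"isopleth level {lvl} outside (0, 1]")


@dataclass(frozen=True)
class LocalHull:
    root: int
    members: tuple[int, ...]
    geometry: BaseGeometry
    area: float
    n_enclosed: int
    degenerate: bool


@dataclass
class UtilizationDistribution:
    animal_id: str
    season: str
    isopleths: dict[float, BaseGeometry]
    areas: dict[float, float]
    centroid: tuple[float, float]
    n_fixes: int
    params: LocohParams

    def polygon(self, level: float) -> BaseGeometry:
        return self.isopleths[level]

    def area(self, level: float) -> float:
        return self.areas[level]


@dataclass(frozen=True)
class SeasonalShift:
    """Between-season range comparison at each isopleth level."""

    overlap_pct: dict[float, float]  # intersection / union, as %
    directional_pct: dict[float, tuple[float, float]]  # (int/first, int/second)
    centroid_distance_km: dict[float, float]

    def mean_directional_pct(self, level: float) -> float:
        d = self.directional_pct[level]
        return 0.5 * (d[0] + d[1])


def _collinear(points: np.ndarray) -> bool:
    if len(points) < 3:
        return True
    p0 = points[0]
    d = points - p0
    cross = d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0]
    return bool(np.allclose(cross, 0.0))


def select_a(points: np.ndarray, quantile: float = 1.0) -> float:
    """Choose the adaptive radius ``a`` as a quantile of all pairwise
    distances (default 1.0, the maximum).

    The source study tuned ``a`` per animal by eye with interactive graph
    tools; that procedure is not reproducible, so this explicit rule stands
    in for it.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points to choose a")
    d = pdist(points)
    return float(np.quantile(d, quantile))


def local_hulls(points: np.ndarray, params: LocohParams) -> list[LocalHull]:
    """Build one local hull per root point.

    For method 'a', neighbours are added in increasing Euclidean distance
    while the running sum of their distances stays within ``a``. Hulls with
    fewer than 3 distinct points are kept as degenerate zero-area geometries
    and flagged.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points")
    if _collinear(points):
        raise ValueError("all points are collinear; hulls would be degenerate")

    dmat = squareform(pdist(points))
    pt_geoms = shapely.points(points)

    hulls = []
    for i in range(n):
        order = np.argsort(dmat[i], kind="stable")
        order = order[order != i]
        dists = dmat[i][order]
        if params.method == "a":
            included = order[np.cumsum(dists) <= params.a]
        elif params.method == "k":
            included = order[: max(params.k - 1, 0)]
        else:  # 'r'
            included = order[dists <= params.r]
        members = (i, *included.tolist())
        geom = MultiPoint(points[list(members)]).convex_hull
        area = float(geom.area)
        degenerate = geom.geom_type != "Polygon"
        n_enclosed = int(np.count_nonzero(shapely.covers(geom, pt_geoms)))
        hulls.append(
            LocalHull(
                root=i,
                members=members,
                geometry=geom,
                area=area,
                n_enclosed=n_enclosed,
                degenerate=degenerate,
            )
        )
    return hulls


def build_isopleths(
    hulls: Sequence[LocalHull],
    points: np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    animal_id: str = "",
    season: str = "",
    params: LocohParams | None = None,
) -> UtilizationDistribution:
    """Accumulate hulls in density order into nested isopleth polygons.

    Hulls are sorted by ascending area, ties broken by more enclosed points
    then root index. The union grows until it covers at least
    ``ceil(level * n)`` points (boundary counts as covered); the isopleth is
    the union at that moment, so polygons are nested and areas monotone in
    level by construction.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    for lvl in levels:
        if not 0.0 < lvl <= 1.0:
            raise ValueError(f"isopleth level {lvl} outside (0, 1]")
    order = sorted(hulls, key=lambda h: (h.area, -h.n_enclosed, h.root))
    pt_geoms = shapely.points(points)

    targets = sorted(levels)
    needed = {lvl: math.ceil(lvl * n) for lvl in targets}
    isopleths: dict[float, BaseGeometry] = {}

    union: BaseGeometry | None = None
    pending = list(targets)
    for h in order:
        union = h.geometry if union is None else union.union(h.geometry)
        covered = int(np.count_nonzero(shapely.covers(union, pt_geoms)))
        while pending and covered >= needed[pending[0]]:
            isopleths[pending[0]] = union
            pending.pop(0)
        if not pending:
            break
    # pathological a values may never reach the target count; close out with
    # the full union rather than failing
    for lvl in pending:
        isopleths[lvl] = union

    areas = {lvl: float(isopleths[lvl].area) for lvl in targets}
    ref_level = max(targets)
    c = isopleths[ref_level].centroid
    return UtilizationDistribution(
        animal_id=animal_id,
        season=season,
        isopleths=isopleths,
        areas=areas,
        centroid=(float(c.x), float(c.y)),
        n_fixes=n,
        params=params or LocohParams(a=1.0),
    )


def estimate_ud(
    points: np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    a: float | None = None,
    a_quantile: float = 1.0,
    animal_id: str = "",
    season: str = "",
) -> UtilizationDistribution:
    """One-call a-LoCoH estimate: choose ``a`` (unless given), build hulls,
    accumulate isopleths."""
    points = np.asarray(points, dtype=float)
    if a is None:
        a = select_a(points, a_quantile)
    params = LocohParams(method="a", a=a, isopleth_levels=tuple(levels))
    hulls = local_hulls(points, params)
    return build_isopleths(
        hulls, points, levels, animal_id=animal_id, season=season, params=params
    )


def seasonal_shift(
    ud_first: UtilizationDistribution, ud_second: UtilizationDistribution
) -> SeasonalShift:
    """Overlap and centroid displacement between two UDs of one animal.

    The source statistic (a single % per animal) is ambiguous, so three
    readings are reported per level: intersection/union, and each directional
    fraction intersection/area(UD). Centroid distance is the Euclidean
    distance between the polygon centroids at that level.
    """
    overlap, directional, cdist = {}, {}, {}
    for lvl in ud_first.isopleths:
        if lvl not in ud_second.isopleths:
            raise ValueError(f"level {lvl} missing from second UD")
        p1, p2 = ud_first.isopleths[lvl], ud_second.isopleths[lvl]
        inter = p1.intersection(p2).area
        union = p1.union(p2).area
        overlap[lvl] = 100.0 * inter / union if union > 0 else 0.0
        directional[lvl] = (
            100.0 * inter / p1.area if p1.area > 0 else 0.0,
            100.0 * inter / p2.area if p2.area > 0 else 0.0,
        )
        c1, c2 = p1.centroid, p2.centroid
        cdist[lvl] = float(np.hypot(c1.x - c2.x, c1.y - c2.y))
    return SeasonalShift(
        overlap_pct=overlap, directional_pct=directional, centroid_distance_km=cdist
    )


@dataclass
class AsymptoteResult:
    asymptote_n: int | None
    curve: list[tuple[int, float]]  # (n fixes, 95% area)
    full_area: float
    reached: bool


def area_asymptote(
    points: np.ndarray,
    min_required: int = 38,
    step: int = 5,
    tolerance: float = 0.05,
    level: float = 0.95,
    a: float | None = None,
    min_confirm: int = 3,
) -> AsymptoteResult:
    """Sample-size diagnostic: recompute the 95% isopleth area on growing
    track prefixes and find the smallest prefix whose area stays within
    ``tolerance`` of the full-data area for every larger prefix.

    ``a`` defaults to the full-data selection so prefixes are comparable.
    A candidate only counts when at least ``min_confirm`` larger prefixes
    confirm it (the last prefix alone is trivially within the band, which
    would let a monotonically expanding track "reach" an asymptote).
    Tracks shorter than ``min_required`` raise (classified "insufficient"
    upstream).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < min_required:
        raise ValueError(f"track has {n} fixes; need at least {min_required}")
    if a is None:
        a = select_a(points)

    sizes = list(range(min_required, n, step))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    curve = []
    for m in sizes:
        ud = estimate_ud(points[:m], levels=(level,), a=a)
        curve.append((m, ud.area(level)))
    full_area = curve[-1][1]

    asymptote_n = None
    if full_area > 0:
        for idx, (m, _) in enumerate(curve):
            if len(curve) - idx - 1 < min_confirm:
                break
            tail = [abs(area / full_area - 1.0) for _, area in curve[idx:]]
            if max(tail) <= tolerance:
                asymptote_n = m
                break
    return AsymptoteResult(
        asymptote_n=asymptote_n,
        curve=curve,
        full_area=full_area,
        reached=asymptote_n is not None,
    )
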