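"""Telemetry ingestion: reading fix tables, projecting coordinates, daily
thinning, season assignment, habitat classification and gross-error QC.

Coordinates are planar kilometres on a local Lambert azimuthal equal-area
plane; areas downstream are first-class outputs, so an equal-area projection
is used rather than UTM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

#: Authalic Earth radius (km) — sphere with the same surface area as WGS84.
EARTH_RADIUS_KM = 6371.0072

#: Offset (hours) added to UTC to obtain the local calendar day used for
#: thinning; the study region sits at UTC-6.
DEFAULT_LOCAL_UTC_OFFSET = -6.0

HABITATS = ("land", "sea", "forest", "unknown")


@dataclass(frozen=True)
class Fix:
    """One telemetry relocation on the local planar grid."""

    animal_id: str
    species: str
    timestamp: datetime
    x: float  # km east
    y: float  # km north
    habitat: str = "unknown"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.animal_id}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat label {self.habitat!r}")


@dataclass
class Track:
    """Time-ordered fix sequence for one animal."""

    animal_id: str
    species: str
    fixes: list[Fix]
    thinned: bool = False

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"track {self.animal_id}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.fixes)

    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in km."""
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float).reshape(-1, 2)

    def times(self) -> list[datetime]:
        return [f.timestamp for f in self.fixes]

    def habitats(self) -> list[str]:
        return [f.habitat for f in self.fixes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "species": self.species,
                "timestamp": [f.timestamp for f in self.fixes],
                "x_km": [f.x for f in self.fixes],
                "y_km": [f.y for f in self.fixes],
                "habitat": [f.habitat for f in self.fixes],
            }
        )


@dataclass(frozen=True)
class SeasonWindow:
    """Half of the yearly partition, delimited by inclusive month-day bounds."""

    label: str
    start: tuple[int, int]  # (month, day), inclusive
    end: tuple[int, int]  # (month, day), inclusive; may wrap the year end


#: Resource seasons: goose season mid-May through October, scarcity otherwise.
DEFAULT_SEASONS = (
    SeasonWindow("summer", (5, 15), (10, 31)),
    SeasonWindow("winter", (11, 1), (5, 14)),
)


def _in_window(month: int, day: int, window: SeasonWindow) -> bool:
    md = (month, day)
    if window.start <= window.end:
        return window.start <= md <= window.end
    # wraps the calendar year
    return md >= window.start or md <= window.end


def assign_season(
    timestamp: datetime | date, windows: Sequence[SeasonWindow] = DEFAULT_SEASONS
) -> str:
    """Return the season label containing ``timestamp``.

    Windows must partition the year; a timestamp matching no window raises.
    """
    for w in windows:
        if _in_window(timestamp.month, timestamp.day, w):
            return w.label
    raise ValueError(f"no season window covers {timestamp}")


def season_instance(
    timestamp: datetime | date, windows: Sequence[SeasonWindow] = DEFAULT_SEASONS
) -> tuple[str, int]:
    """Return ``(label, year)`` where a wrapping window is tagged with the
    year in which it starts (a winter beginning in November keeps that year
    through the following spring)."""
    label = assign_season(timestamp, windows)
    window = next(w for w in windows if w.label == label)
    year = timestamp.year
    if window.start > window.end and (timestamp.month, timestamp.day) <= window.end:
        year -= 1
    return label, year


# ---------------------------------------------------------------------------
# Projection


@dataclass(frozen=True)
class Projection:
    """Lambert azimuthal equal-area projection on the authalic sphere,
    centred on (lon0, lat0); emits kilometres."""

    lon0: float
    lat0: float

    def forward(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return x, y


REQUIRED_COLUMNS = ("animal_id", "species", "timestamp")


def read_telemetry(
    path,
    projection: Projection | None = None,
) -> tuple[list[Track], pd.DataFrame]:
    """Read a telemetry CSV into tracks.

    The file must carry ``animal_id, species, timestamp`` plus either
    ``lon, lat`` (projected here) or ``x_km, y_km`` (passed through).
    An optional ``habitat`` column is honoured. Malformed rows are returned
    in a rejection table rather than silently dropped.

    Returns ``(tracks, rejected)`` where ``rejected`` has the offending rows
    plus a ``reason`` column.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "species": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    geographic = {"lon", "lat"}.issubset(df.columns)
    planar = {"x_km", "y_km"}.issubset(df.columns)
    if not (geographic or planar):
        raise ValueError("need either lon/lat or x_km/y_km columns")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    cx, cy = ("lon", "lat") if geographic else ("x_km", "y_km")
    xs = pd.to_numeric(df[cx], errors="coerce")
    ys = pd.to_numeric(df[cy], errors="coerce")

    bad = ts.isna() | xs.isna() | ys.isna()
    reasons = np.select(
        [ts.isna(), xs.isna() | ys.isna()],
        ["unparseable timestamp", "missing coordinate"],
        default="",
    )
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad.to_numpy()]

    good = df.loc[~bad].copy()
    good["timestamp"] = ts[~bad]
    if geographic:
        if projection is None:
            projection = Projection(
                lon0=float(xs[~bad].mean()), lat0=float(ys[~bad].mean())
            )
        px, py = projection.forward(xs[~bad].to_numpy(), ys[~bad].to_numpy())
        good["x_km"], good["y_km"] = px, py
    else:
        good["x_km"], good["y_km"] = xs[~bad], ys[~bad]
    if "habitat" not in good.columns:
        good["habitat"] = "unknown"

    tracks = []
    for (animal, species), grp in good.groupby(["animal_id", "species"], sort=True):
        grp = grp.sort_values("timestamp")
        fixes = [
            Fix(
                animal_id=animal,
                species=species,
                timestamp=t.to_pydatetime(),
                x=float(x),
                y=float(y),
                habitat=h if h in HABITATS else "unknown",
            )
            for t, x, y, h in zip(
                grp["timestamp"], grp["x_km"], grp["y_km"], grp["habitat"]
            )
        ]
        tracks.append(Track(animal_id=animal, species=species, fixes=fixes))
    return tracks, rejected


def write_telemetry(tracks: Iterable[Track], path) -> None:
    """Write tracks in the CSV dialect that :func:`read_telemetry` accepts."""
    frames = [t.to_frame() for t in tracks]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["animal_id", "species", "timestamp", "x_km", "y_km", "habitat"]
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Thinning


def _animal_stream(master_seed: int, animal_id: str) -> np.random.Generator:
    # independent per-animal streams: adding an animal never reshuffles another
    digest = hashlib.sha256(animal_id.encode("utf8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def _local_day(ts: datetime, utc_offset_hours: float) -> date:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return (ts.astimezone(timezone.utc) + timedelta(hours=utc_offset_hours)).date()


def thin_daily(
    track: Track,
    seed: int,
    utc_offset_hours: float = DEFAULT_LOCAL_UTC_OFFSET,
) -> Track:
    """Keep one uniformly random fix per local calendar day.

    Deterministic given ``seed``; idempotent on already-thinned tracks
    (a day with a single fix always keeps that fix).
    """
    if not track.fixes:
        raise ValueError(f"track {track.animal_id} is empty")
    rng = _animal_stream(seed, track.animal_id)
    days: dict[date, list[int]] = {}
    for i, f in enumerate(track.fixes):
        days.setdefault(_local_day(f.timestamp, utc_offset_hours), []).append(i)
    keep = sorted(
        idxs[rng.integers(0, len(idxs))] for d, idxs in sorted(days.items())
    )
    return replace(track, fixes=[track.fixes[i] for i in keep], thinned=True)


def mean_interval_hours(track: Track) -> float:
    """Mean spacing between successive fixes, in hours."""
    ts = track.times()
    if len(ts) < 2:
        return float("nan")
    deltas = [(b - a).total_seconds() / 3600.0 for a, b in zip(ts, ts[1:])]
    return float(np.mean(deltas))


# ---------------------------------------------------------------------------
# Habitat and QC


def classify_habitat(fix: Fix, world, timestamp: datetime | None = None) -> tuple[str, bool]:
    """Point-in-polygon habitat label for one fix.

    Ties on shared boundaries resolve in polygon order land > forest > sea
    (a fix exactly on the coastline is land). Returns ``(label, implausible)``
    where ``implausible`` marks a sea fix dated outside the ice window.
    """
    p = Point(fix.x, fix.y)
    ts = timestamp or fix.timestamp
    if world.land_polygon.covers(p):
        return "land", False
    if world.forest_polygon is not None and world.forest_polygon.covers(p):
        return "forest", False
    if world.sea_polygon.covers(p):
        return "sea", not world.ice_available(ts)
    return "unknown", False


def qc_speed_filter(
    track: Track, max_kmh: float = float("inf")
) -> tuple[Track, list[Fix]]:
    """Drop fixes implying impossible speed to *both* neighbours.

    The study screened gross location errors visually; this is the explicit
    stand-in, default off (infinite threshold). Removals are returned, not
    merely counted.
    """
    fixes = track.fixes
    if len(fixes) < 3 or not np.isfinite(max_kmh):
        return track, []

    def speed(a: Fix, b: Fix) -> float:
        dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
        if dt_h <= 0:
            return float("inf")
        return float(np.hypot(b.x - a.x, b.y - a.y)) / dt_h

    rejected = []
    kept = [fixes[0]]
    for prev, cur, nxt in zip(fixes, fixes[1:], fixes[2:]):
        if speed(prev, cur) > max_kmh and speed(cur, nxt) > max_kmh:
            rejected.append(cur)
        else:
            kept.append(cur)
    kept.append(fixes[-1])
    return replace(track, fixes=kept), rejected
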