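"""Spring-timing vs previous-autumn juvenile counts, and recovery speeds.

The juvenile count is first normalized to a 50-net season and square-root
transformed; each spring's anomaly is regressed on the transformed count
from the autumn of the preceding calendar year.  Configured outlier autumns
are excluded by year, not by an automated rule.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError

__all__ = [
    "RecoveryPair",
    "JuvenileRegression",
    "juvenile_regression",
    "pearson",
    "mean_migration_speed",
    "load_recoveries",
    "haversine_km",
]

_EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two decimal-degree points (spherical earth)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class RecoveryPair:
    """A direct recovery: ringed then re-encountered within one migration."""

    ring_date: dt.date
    find_date: dt.date
    distance_km: float

    def __post_init__(self):
        if self.find_date <= self.ring_date:
            raise DomainError("find_date must be after ring_date")
        if self.distance_km < 0:
            raise DomainError("distance must be non-negative")

    @property
    def elapsed_days(self) -> int:
        return (self.find_date - self.ring_date).days

    @property
    def speed_kmd(self) -> float:
        return self.distance_km / self.elapsed_days


@dataclass(frozen=True)
class JuvenileRegression:
    period: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_raw: float


def juvenile_regression(
    aa: dict[int, float] | pd.Series,
    njuv_per50: dict[int, float] | pd.Series,
    exclude_autumn_years: list[int] | tuple[int, ...] = (),
    period: str = "AA",
) -> JuvenileRegression:
    """OLS of a spring anomaly on sqrt(previous autumn's per-50-nets count).

    Spring year ``y`` is paired with autumn year ``y - 1``.  Years whose
    previous autumn is listed in ``exclude_autumn_years`` are dropped.
    """
    aa = pd.Series(aa, dtype=float)
    njuv = pd.Series(njuv_per50, dtype=float)
    if (njuv < 0).any():
        raise DomainError("per-50-nets counts must be non-negative")
    rows = []
    for year, value in aa.items():
        autumn = int(year) - 1
        if autumn in exclude_autumn_years or autumn not in njuv.index:
            continue
        rows.append((year, value, math.sqrt(njuv.loc[autumn])))
    if len(rows) < 3:
        raise DomainError(f"only {len(rows)} paired years; need >= 3")
    _, y, x = map(np.asarray, zip(*rows))
    if np.std(x) <= 0:
        raise DomainError("zero-variance predictor (constant juvenile counts)")
    lr = stats.linregress(x, y)
    return JuvenileRegression(
        period=period,
        n=len(rows),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=float(lr.rvalue**2),
        p_raw=float(lr.pvalue),
    )


def pearson(x: dict[int, float] | pd.Series, y: dict[int, float] | pd.Series) -> tuple[float, float]:
    """Product-moment correlation over shared years, two-sided t-based p."""
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    common = xs.index.intersection(ys.index)
    if len(common) < 3:
        raise DomainError(f"only {len(common)} paired values; need >= 3")
    xa, ya = np.asarray(xs.loc[common]), np.asarray(ys.loc[common])
    if np.std(xa) <= 0 or np.std(ya) <= 0:
        raise DomainError("zero-variance input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def mean_migration_speed(pairs: list[RecoveryPair]) -> float:
    """Mean of per-pair displacement speeds (km/day)."""
    if not pairs:
        raise DomainError("no recovery pairs supplied")
    return float(np.mean([p.speed_kmd for p in pairs]))


def load_recoveries(path: str | Path) -> list[RecoveryPair]:
    """Read a recovery CSV with dates plus a distance or two coordinate pairs.

    Required columns: ``ring_date``, ``find_date`` (ISO 8601), and either
    ``distance_km`` or all of ``ring_lat, ring_lon, find_lat, find_lon``.
    Elapsed times shorter than a day are rounded up to one day by using the
    calendar-day difference.
    """
    frame = pd.read_csv(path, comment="#")
    if "ring_date" not in frame.columns or "find_date" not in frame.columns:
        raise ConfigError(f"{path}: need ring_date and find_date columns")
    has_dist = "distance_km" in frame.columns
    coord_cols = ["ring_lat", "ring_lon", "find_lat", "find_lon"]
    has_coords = all(c in frame.columns for c in coord_cols)
    if not (has_dist or has_coords):
        raise ConfigError(f"{path}: need distance_km or coordinate columns {coord_cols}")
    pairs = []
    for row in frame.itertuples(index=False):
        ring = dt.date.fromisoformat(str(row.ring_date))
        find = dt.date.fromisoformat(str(row.find_date))
        if has_dist and not pd.isna(getattr(row, "distance_km")):
            dist = float(getattr(row, "distance_km"))
        else:
            dist = haversine_km(
                float(row.ring_lat), float(row.ring_lon),
                float(row.find_lat), float(row.find_lon),
            )
        pairs.append(RecoveryPair(ring_date=ring, find_date=find, distance_km=dist))
    return pairs
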