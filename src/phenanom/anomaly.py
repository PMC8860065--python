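"""Cumulative arrival curves and the annual timing anomaly in days.

A season's daily counts are converted to cumulative percentages of the
season total; an equal-weight mean over years gives the multiyear baseline
curve.  The annual anomaly (AA) over a day range is the summed daily gap
between the baseline and a year's curve, divided by 100 — a signed timing
statistic in days where, under the default sign convention, positive means
passage later than the baseline.

Percentile thresholds on the baseline bind percentage ranges to concrete
day ranges, which decompose AA into three non-overlapping main periods
(MP1–MP3) and nine overlapping sub-periods (SP1–SP9).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .ringing import SeasonCounts, SeasonWindow

__all__ = [
    "CumCurve",
    "PeriodSpec",
    "AnomalyValue",
    "MAIN_PERIOD_RANGES",
    "SUB_PERIOD_RANGES",
    "cumulative_percent",
    "multiyear_baseline",
    "annual_anomaly",
    "percentile_date",
    "build_periods",
    "decompose",
    "anomaly_table",
    "period_table",
]

#: Percentile ranges for the three contiguous main periods (thirds of passage).
MAIN_PERIOD_RANGES: list[tuple[str, int, int]] = [
    ("MP1", 0, 33),
    ("MP2", 34, 66),
    ("MP3", 67, 100),
]

#: Percentile ranges for the nine overlapping 20-point sub-period windows.
SUB_PERIOD_RANGES: list[tuple[str, int, int]] = [
    ("SP1", 0, 20),
    ("SP2", 11, 30),
    ("SP3", 21, 40),
    ("SP4", 31, 50),
    ("SP5", 41, 60),
    ("SP6", 51, 70),
    ("SP7", 61, 80),
    ("SP8", 71, 90),
    ("SP9", 81, 100),
]

FULL_RANGE: tuple[str, int, int] = ("AA", 0, 100)


@dataclass(frozen=True)
class CumCurve:
    """Cumulative percentage curve over a season window.

    ``owner`` is the year, or the string ``"baseline"`` for the multiyear
    mean curve.
    """

    owner: int | str
    values: tuple[float, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise DomainError("curve must be a non-empty 1-d vector")
        if np.any(np.diff(vals) < -1e-9):
            raise DomainError("cumulative curve must be non-decreasing")
        if vals[0] < -1e-9 or vals[-1] > 100 + 1e-9:
            raise DomainError("curve values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class PeriodSpec:
    """A percentile range bound to an inclusive day-index range."""

    label: str
    pct_lo: int
    pct_hi: int
    day_lo: int
    day_hi: int

    def __post_init__(self):
        if not self.pct_lo < self.pct_hi:
            raise DomainError(f"{self.label}: pct_lo must be < pct_hi")
        if self.day_lo > self.day_hi:
            raise DomainError(f"{self.label}: empty day span [{self.day_lo}, {self.day_hi}]")

    @property
    def n_days(self) -> int:
        return self.day_hi - self.day_lo + 1


@dataclass(frozen=True)
class AnomalyValue:
    year: int
    period: str
    aa_days: float


def cumulative_percent(season: SeasonCounts) -> CumCurve:
    """Running sum of daily percentages of the season total.

    Raises
    ------
    DomainError
        If the season total is zero (such seasons must be filtered first).
    """
    if season.total <= 0:
        raise DomainError(f"season {season.year} has zero captures")
    cum = np.cumsum(season.counts) * (100.0 / season.total)
    cum[-1] = 100.0  # exact endpoint, guard against float drift
    return CumCurve(owner=season.year, values=tuple(cum))


def multiyear_baseline(curves: list[CumCurve]) -> CumCurve:
    """Equal-weight elementwise mean of at least two year curves."""
    if len(curves) < 2:
        raise DomainError("baseline needs at least 2 year curves")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise DomainError(f"curves have mismatched lengths {sorted(lengths)}")
    mean = np.mean([c.as_array() for c in curves], axis=0)
    return CumCurve(owner="baseline", values=tuple(mean))


def annual_anomaly(
    curve: CumCurve,
    baseline: CumCurve,
    day_lo: int,
    day_hi: int,
    sign: int = 1,
) -> float:
    """Summed daily (baseline − curve) gap over an inclusive day range, /100.

    With ``sign=+1`` (default) a positive value means the year's passage ran
    later than the baseline within the range; ``sign=-1`` flips the
    convention.
    """
    if len(curve) != len(baseline):
        raise DomainError("curve and baseline lengths differ")
    if not (0 <= day_lo <= day_hi < len(curve)):
        raise DomainError(f"invalid day range [{day_lo}, {day_hi}] for length {len(curve)}")
    if sign not in (1, -1):
        raise DomainError("sign must be +1 or -1")
    b = baseline.as_array()[day_lo : day_hi + 1]
    c = curve.as_array()[day_lo : day_hi + 1]
    return sign * float(np.sum(b - c)) / 100.0


def percentile_date(baseline: CumCurve, q: float) -> int:
    """First day index where the baseline reaches ``q`` percent."""
    if not 0 < q <= 100:
        raise DomainError(f"percentile must be in (0, 100], got {q}")
    vals = baseline.as_array()
    hits = np.nonzero(vals >= q - 1e-9)[0]
    if hits.size == 0:
        raise DomainError(f"baseline never reaches {q}% (ends at {vals[-1]:.3f})")
    return int(hits[0])


def build_periods(
    baseline: CumCurve,
    ranges: list[tuple[str, int, int]],
    mode: str = "overlap",
) -> list[PeriodSpec]:
    """Bind percentile ranges to day ranges on the baseline curve.

    ``mode="partition"`` produces contiguous, non-overlapping periods: each
    period starts the day after the previous upper percentile is reached
    (the main-period thirds exactly tile the window).  ``mode="overlap"``
    starts each period at the first crossing of its own lower percentile
    (the sub-period grid; ranges may share days).
    """
    if mode not in ("partition", "overlap"):
        raise DomainError(f"unknown mode {mode!r}")
    periods: list[PeriodSpec] = []
    prev_hi_day = -1
    for label, lo, hi in ranges:
        day_hi = percentile_date(baseline, hi)
        if lo == 0:
            day_lo = 0
        elif mode == "partition":
            day_lo = prev_hi_day + 1
        else:
            day_lo = percentile_date(baseline, lo)
        if day_lo > day_hi:
            raise DomainError(f"period {label}: empty day span [{day_lo}, {day_hi}]")
        periods.append(PeriodSpec(label=label, pct_lo=lo, pct_hi=hi, day_lo=day_lo, day_hi=day_hi))
        prev_hi_day = day_hi
    return periods


def decompose(
    curve: CumCurve,
    baseline: CumCurve,
    periods: list[PeriodSpec],
    sign: int = 1,
) -> list[AnomalyValue]:
    """Annual anomaly of one year's curve within each period."""
    year = curve.owner
    return [
        AnomalyValue(
            year=year,
            period=p.label,
            aa_days=annual_anomaly(curve, baseline, p.day_lo, p.day_hi, sign=sign),
        )
        for p in periods
    ]


def anomaly_table(
    curves: list[CumCurve],
    baseline: CumCurve,
    periods: list[PeriodSpec],
    sign: int = 1,
) -> pd.DataFrame:
    """Long (year, period, aa_days) frame over all years and periods."""
    rows = [
        {"year": av.year, "period": av.period, "aa_days": av.aa_days}
        for curve in curves
        for av in decompose(curve, baseline, periods, sign=sign)
    ]
    return pd.DataFrame(rows, columns=["year", "period", "aa_days"])


def period_table(periods: list[PeriodSpec], window: SeasonWindow, year: int = 2001) -> pd.DataFrame:
    """Period date-range table with calendar dates for a reference year."""
    start = window.start_date(year)
    rows = []
    for p in periods:
        rows.append(
            {
                "period": p.label,
                "pct_lo": p.pct_lo,
                "pct_hi": p.pct_hi,
                "day_lo": p.day_lo,
                "day_hi": p.day_hi,
                "date_lo": (start + dt.timedelta(days=p.day_lo)).strftime("%d %b"),
                "date_hi": (start + dt.timedelta(days=p.day_hi)).strftime("%d %b"),
            }
        )
    return pd.DataFrame(rows)
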