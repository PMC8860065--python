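"""Capture-table ingestion and per-season daily count series.

Reads delimited capture tables (one bird capture per row), deduplicates to
the first capture of each individual within a season window, tallies daily
totals over fixed calendar windows, applies the minimum-total season filter
and computes the effort-normalized juvenile index.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError, DomainError, RowParseError

__all__ = [
    "AgeClass",
    "CaptureRecord",
    "SeasonWindow",
    "SPRING",
    "AUTUMN",
    "SeasonCounts",
    "EffortIndex",
    "load_captures",
    "load_effort",
    "first_captures",
    "daily_counts",
    "filter_seasons",
    "juveniles_per_50_nets",
    "season_counts_frame",
]


class AgeClass(enum.Enum):
    FULL_GROWN = "full_grown"
    JUVENILE = "juvenile"
    ADULT = "adult"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, raw: str) -> "AgeClass":
        key = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "full_grown": cls.FULL_GROWN,
            "fullgrown": cls.FULL_GROWN,
            "fg": cls.FULL_GROWN,
            "juvenile": cls.JUVENILE,
            "juv": cls.JUVENILE,
            "adult": cls.ADULT,
            "ad": cls.ADULT,
            "unknown": cls.UNKNOWN,
            "": cls.UNKNOWN,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unrecognised age class {raw!r}") from None


@dataclass(frozen=True)
class CaptureRecord:
    """A single capture event of a ringed bird."""

    ring_id: str
    capture_date: dt.date
    age_class: AgeClass = AgeClass.UNKNOWN
    site: str = ""
    season_nets: int | None = None


@dataclass(frozen=True)
class SeasonWindow:
    """A fixed month-day calendar window, identical every year."""

    label: str
    start: tuple[int, int]  # (month, day)
    end: tuple[int, int]

    def __post_init__(self):
        if self.start >= self.end:
            raise DomainError(f"window start {self.start} must precede end {self.end}")

    def start_date(self, year: int) -> dt.date:
        return dt.date(year, *self.start)

    def end_date(self, year: int) -> dt.date:
        return dt.date(year, *self.end)

    def n_days(self, year: int = 2001) -> int:
        # 2001 is an arbitrary non-leap year; both standard windows start
        # after February so leap days never change the day count.
        return (self.end_date(year) - self.start_date(year)).days + 1

    def contains(self, date: dt.date) -> bool:
        return self.start_date(date.year) <= date <= self.end_date(date.year)

    def day_index(self, date: dt.date) -> int:
        """0-based position of ``date`` within the window of its own year."""
        if not self.contains(date):
            raise DomainError(f"{date} outside window {self.label}")
        return (date - self.start_date(date.year)).days

    def dates(self, year: int) -> list[dt.date]:
        start = self.start_date(year)
        return [start + dt.timedelta(days=i) for i in range(self.n_days(year))]


SPRING = SeasonWindow("spring", (4, 1), (5, 15))   # 45 days
AUTUMN = SeasonWindow("autumn", (8, 14), (10, 29))  # 77 days


@dataclass
class SeasonCounts:
    """Daily capture totals for one (year, window)."""

    year: int
    window: SeasonWindow
    counts: list[int] = field(default_factory=list)

    def __post_init__(self):
        expected = self.window.n_days(self.year)
        if len(self.counts) != expected:
            raise DomainError(
                f"counts length {len(self.counts)} != window length {expected}"
            )
        if any(c < 0 for c in self.counts):
            raise DomainError("daily counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class EffortIndex:
    """Juveniles caught per autumn, normalized to a 50-net season."""

    year: int
    juvenile_total: int
    nets: int

    @property
    def per50(self) -> float:
        return juveniles_per_50_nets(self.juvenile_total, self.nets)


_DEFAULT_SCHEMA = {
    "ring_id": "ring_id",
    "date": "date",
    "age_class": "age_class",
    "site": "site",
}


def load_captures(path: str | Path, schema: dict[str, str] | None = None) -> list[CaptureRecord]:
    """Read a capture CSV into records, aborting on any malformed row.

    Parameters
    ----------
    path:
        Delimited text file with one capture per row.
    schema:
        Map from the canonical column roles (``ring_id``, ``date``,
        ``age_class``, ``site``) to the column names present in the file.
        Defaults to identity.

    Raises
    ------
    ConfigError
        If a required column cannot be mapped.
    RowParseError
        Listing every row whose date or age class failed to parse.
    """
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    frame = pd.read_csv(path, dtype=str, comment="#")
    for role in ("ring_id", "date"):
        if schema[role] not in frame.columns:
            raise ConfigError(
                f"required column {schema[role]!r} (role {role}) missing from {path}"
            )
    has_age = schema["age_class"] in frame.columns
    has_site = schema["site"] in frame.columns

    records: list[CaptureRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is row 1
        raw = dict(zip(frame.columns, row))
        try:
            date = dt.date.fromisoformat(str(raw[schema["date"]]).strip())
        except ValueError:
            problems.append((i, f"unparseable date {raw[schema['date']]!r}"))
            continue
        try:
            age = AgeClass.parse(raw[schema["age_class"]]) if has_age else AgeClass.UNKNOWN
        except ValueError as exc:
            problems.append((i, str(exc)))
            continue
        records.append(
            CaptureRecord(
                ring_id=str(raw[schema["ring_id"]]).strip(),
                capture_date=date,
                age_class=age,
                site=str(raw[schema["site"]]).strip() if has_site else "",
            )
        )
    if problems:
        raise RowParseError(problems)
    return records


def load_effort(path: str | Path) -> pd.DataFrame:
    """Read the per-season effort table (year, season, nets)."""
    frame = pd.read_csv(path, comment="#")
    required = {"year", "season", "nets"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"effort table missing columns {sorted(missing)}")
    if (frame["nets"] <= 0).any():
        raise DomainError("nets must be positive")
    return frame


def first_captures(
    records: list[CaptureRecord], window: SeasonWindow, year: int
) -> list[CaptureRecord]:
    """Keep, per ring id, only the first capture inside (year, window).

    Records outside the window (or in other years) are dropped.  The result
    is sorted by date then ring id, so the operation is a pure function of
    the input *set* of records.
    """
    in_window = [
        r
        for r in records
        if r.capture_date.year == year and window.contains(r.capture_date)
    ]
    best: dict[str, CaptureRecord] = {}
    for rec in sorted(in_window, key=lambda r: (r.capture_date, r.ring_id)):
        best.setdefault(rec.ring_id, rec)
    return sorted(best.values(), key=lambda r: (r.capture_date, r.ring_id))


def daily_counts(
    records: list[CaptureRecord], window: SeasonWindow, year: int
) -> SeasonCounts:
    """Tally deduplicated records into one count per window day."""
    counts = [0] * window.n_days(year)
    for rec in records:
        if rec.capture_date.year == year and window.contains(rec.capture_date):
            counts[window.day_index(rec.capture_date)] += 1
    return SeasonCounts(year=year, window=window, counts=counts)


def filter_seasons(
    all_counts: list[SeasonCounts], min_total: int = 30
) -> tuple[list[SeasonCounts], list[int]]:
    """Split seasons into (total >= min_total) and the excluded years.

    Inclusion is ``total >= min_total``: the rule that excludes exactly the
    seasons with fewer than ``min_total`` captures.
    """
    if min_total < 0:
        raise DomainError("min_total must be >= 0")
    included = [s for s in all_counts if s.total >= min_total]
    excluded_years = sorted(s.year for s in all_counts if s.total < min_total)
    return included, excluded_years


def juveniles_per_50_nets(juvenile_total: int, nets: int) -> float:
    """Effort-normalized juvenile count: total / nets * 50."""
    if nets <= 0:
        raise DomainError(f"nets must be positive, got {nets}")
    if juvenile_total < 0:
        raise DomainError("juvenile_total must be non-negative")
    return juvenile_total / nets * 50.0


def season_counts_frame(seasons: list[SeasonCounts]) -> pd.DataFrame:
    """Tidy (year, day_index, date, count) frame for export."""
    rows = []
    for s in seasons:
        for i, (date, c) in enumerate(zip(s.window.dates(s.year), s.counts)):
            rows.append({"year": s.year, "day_index": i, "date": date.isoformat(), "count": c})
    return pd.DataFrame(rows, columns=["year", "day_index", "date", "count"])
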