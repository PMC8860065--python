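"""Monthly climate index series → per-year seasonal-mean covariates.

Each covariate is a named (index, month window, year lag) triple: e.g. the
Aug–Oct mean of the previous year's Southern Oscillation Index.  The
Nov–Mar window straddles the calendar year boundary: Nov–Dec are read from
the year before the nominal covariate year.  A one-year lag shifts the
whole window back an additional calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, MissingDataError

__all__ = [
    "ClimateSeries",
    "VariableSpec",
    "ClimateVariable",
    "DEFAULT_ROSTER",
    "CORE_NINE",
    "load_monthly",
    "seasonal_mean",
    "build_covariates",
    "standardize",
    "collinearity_screen",
]


@dataclass
class ClimateSeries:
    """A monthly climate index: (year, month) → value."""

    index_name: str
    observations: dict[tuple[int, int], float] = field(default_factory=dict)

    def add(self, year: int, month: int, value: float) -> None:
        if not 1 <= month <= 12:
            raise DomainError(f"month {month} out of range")
        key = (int(year), int(month))
        if key in self.observations:
            raise DomainError(f"duplicate observation for {self.index_name} {key}")
        self.observations[key] = float(value)

    def get(self, year: int, month: int) -> float:
        try:
            return self.observations[(year, month)]
        except KeyError:
            raise MissingDataError(
                f"missing {self.index_name} value for year {year}, month {month}"
            ) from None


@dataclass(frozen=True)
class VariableSpec:
    """Definition of one seasonal-mean covariate."""

    name: str
    source: str
    months: tuple[int, ...]
    lag_years: int = 0


@dataclass
class ClimateVariable:
    """A realized covariate: per-year values, optionally standardized."""

    spec: VariableSpec
    values: dict[int, float]
    standardized: bool = False

    @property
    def name(self) -> str:
        return self.spec.name


APR_MAY = (4, 5)
JUN_JUL = (6, 7)
AUG_OCT = (8, 9, 10)
NOV_MAR = (11, 12, 1, 2, 3)

#: The 15-covariate roster (names follow the index + window + lag pattern).
DEFAULT_ROSTER: tuple[VariableSpec, ...] = (
    VariableSpec("TLEB APR-MAY", "TLEB", APR_MAY, 0),
    VariableSpec("NAO APR-MAY", "NAO", APR_MAY, 0),
    VariableSpec("SCAND APR-MAY", "SCAND", APR_MAY, 0),
    VariableSpec("NAO NOV-MAR", "NAO", NOV_MAR, 0),
    VariableSpec("PSAH NOV-MAR", "PSAH", NOV_MAR, 0),
    VariableSpec("TSAH NOV-MAR", "TSAH", NOV_MAR, 0),
    VariableSpec("IOD NOV-MAR", "IOD", NOV_MAR, 0),
    VariableSpec("SOI NOV-MAR", "SOI", NOV_MAR, 0),
    VariableSpec("NAO AUG-OCT_1y", "NAO", AUG_OCT, 1),
    VariableSpec("PSAH AUG-OCT_1y", "PSAH", AUG_OCT, 1),
    VariableSpec("TSAH AUG-OCT_1y", "TSAH", AUG_OCT, 1),
    VariableSpec("IOD AUG-OCT_1y", "IOD", AUG_OCT, 1),
    VariableSpec("SOI AUG-OCT_1y", "SOI", AUG_OCT, 1),
    VariableSpec("NAO JUN-JUL_1y", "NAO", JUN_JUL, 1),
    VariableSpec("SCAND JUN-JUL_1y", "SCAND", JUN_JUL, 1),
)

#: The nine-covariate core used for the moving-window profile.
CORE_NINE: tuple[str, ...] = (
    "TLEB APR-MAY",
    "NAO APR-MAY",
    "NAO NOV-MAR",
    "PSAH NOV-MAR",
    "PSAH AUG-OCT_1y",
    "TSAH AUG-OCT_1y",
    "IOD AUG-OCT_1y",
    "SOI AUG-OCT_1y",
    "SCAND JUN-JUL_1y",
)


def load_monthly(path: str | Path) -> dict[str, ClimateSeries]:
    """Read monthly series from a CSV file or a directory of CSV files.

    Expected columns: ``index_name, year, month, value``.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise ConfigError(f"no climate CSV files found under {path}")
    out: dict[str, ClimateSeries] = {}
    for f in files:
        frame = pd.read_csv(f, comment="#")
        missing = {"index_name", "year", "month", "value"} - set(frame.columns)
        if missing:
            raise ConfigError(f"{f}: missing columns {sorted(missing)}")
        for row in frame.itertuples(index=False):
            series = out.setdefault(str(row.index_name), ClimateSeries(str(row.index_name)))
            series.add(int(row.year), int(row.month), float(row.value))
    return out


def _window_straddles(months: tuple[int, ...]) -> bool:
    # A window wraps the year boundary iff it contains both December and
    # January (Nov–Mar is the only such window in the default roster).
    return 12 in months and 1 in months


def seasonal_mean(
    series: ClimateSeries, months: tuple[int, ...], lag_years: int, year: int
) -> float:
    """Mean of the monthly values in the (possibly straddling) window.

    For a straddling window (Nov–Mar), months >= 11 are read from the year
    before the nominal year.  ``lag_years`` then shifts every month back by
    whole calendar years.
    """
    straddle = _window_straddles(months)
    vals = []
    for m in months:
        obs_year = year - lag_years - (1 if straddle and m >= 11 else 0)
        vals.append(series.get(obs_year, m))
    return float(np.mean(vals))


def build_covariates(
    series_map: dict[str, ClimateSeries],
    years: list[int],
    roster: tuple[VariableSpec, ...] = DEFAULT_ROSTER,
) -> pd.DataFrame:
    """Raw (unstandardized) year × variable covariate matrix.

    Raises :class:`MissingDataError` naming the first absent observation.
    """
    data: dict[str, list[float]] = {}
    for spec in roster:
        if spec.source not in series_map:
            raise MissingDataError(f"climate index {spec.source!r} not provided")
        series = series_map[spec.source]
        data[spec.name] = [
            seasonal_mean(series, spec.months, spec.lag_years, y) for y in years
        ]
    return pd.DataFrame(data, index=pd.Index(list(years), name="year"))


def standardize(values: pd.Series | dict[int, float]) -> pd.Series:
    """Z-scores over the provided years (ddof=1 sample SD); mean 0, sd 1."""
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise DomainError("standardization needs at least 2 values")
    sd = s.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise DomainError("cannot standardize a zero-variance series")
    return (s - s.mean()) / sd


def standardize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.apply(standardize, axis=0)


def collinearity_screen(
    frame: pd.DataFrame,
    contributions: dict[str, float],
    r_threshold: float = 0.7,
    order: tuple[str, ...] | None = None,
) -> list[str]:
    """Greedily drop the lower-contribution member of highly correlated pairs.

    Repeatedly removes the lowest-contribution variable involved in any pair
    with ``|r| >= r_threshold`` until no violating pair remains.  Ties on
    contribution are broken by roster ``order`` (earlier wins, i.e. the
    later-listed variable is dropped).
    """
    names = list(frame.columns)
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ConfigError(f"contributions missing for {missing}")
    order = order or tuple(names)
    rank = {n: i for i, n in enumerate(order)}
    corr = frame.corr().abs()

    retained = list(names)
    while True:
        violating = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if corr.loc[a, b] >= r_threshold - 1e-12
        ]
        if not violating:
            return retained
        involved = sorted(
            {v for pair in violating for v in pair},
            key=lambda n: (contributions[n], -rank.get(n, len(rank))),
        )
        retained.remove(involved[0])
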