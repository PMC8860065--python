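"""Seeded synthetic study generator with recoverable ground truth.

Emulates multi-cohort spring passage: each cohort's mean transit day moves
linearly with standardized climate covariates (known day-per-SD effects),
optionally drifts over years, and daily counts are multinomial draws from a
window-truncated Gaussian-mixture density.  The generator also emits autumn
juvenile captures with varying net effort and monthly climate CSVs in the
exact dialects the ingestion modules read, so the whole pipeline can be
exercised end to end without external data.

Randomness uses one root seed with named substreams per (component, year),
so adding a year never perturbs earlier years' draws.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .climate import APR_MAY, AUG_OCT, JUN_JUL, NOV_MAR, ClimateSeries, VariableSpec, seasonal_mean
from .errors import ConfigError
from .ringing import AUTUMN, SPRING, SeasonCounts, SeasonWindow

__all__ = [
    "CohortSpec",
    "ClimateSpec",
    "ScenarioConfig",
    "TruthBundle",
    "substream",
    "synthetic_roster",
    "gen_climate",
    "gen_passage",
    "expected_density",
    "gen_study",
]


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent generator keyed by the root seed and a name path."""
    entropy = [int(seed) & 0xFFFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class CohortSpec:
    """One migratory cohort of the passage mixture."""

    weight: float
    base_mean_day: float          # 0-based day index within the window
    sd_days: float
    effects: dict[str, float] = field(default_factory=dict)  # variable -> days per SD
    trend_days_per_year: float = 0.0

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ConfigError("cohort weight must be in (0, 1]")
        if self.sd_days <= 0:
            raise ConfigError("cohort sd_days must be positive")


@dataclass(frozen=True)
class ClimateSpec:
    """Generator spec for one synthetic seasonal covariate."""

    mean: float = 0.0
    sd: float = 1.0
    trend: float = 0.0  # per-year linear drift of the seasonal mean


@dataclass
class ScenarioConfig:
    n_years: int = 36
    start_year: int = 1982
    window: SeasonWindow = SPRING
    cohorts: list[CohortSpec] = field(default_factory=list)
    climate: dict[str, ClimateSpec] = field(default_factory=dict)
    season_total_mean: float = 250.0
    season_total_dispersion: float | None = None  # NB size; None -> Poisson
    low_count_years: dict[int, int] = field(default_factory=dict)
    recapture_fraction: float = 0.0
    autumn_juv_mean: float = 600.0
    autumn_juv_sd: float = 150.0
    autumn_nets_range: tuple[int, int] = (38, 76)
    spring_nets: int = 50
    juvenile_effect_days_per_sd: float = 0.0
    max_truncated_mass: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 5:
            raise ConfigError("n_years must be >= 5")
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        wsum = sum(c.weight for c in self.cohorts)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigError(f"cohort weights sum to {wsum}, expected 1")
        for c in self.cohorts:
            for v in c.effects:
                if v not in self.climate:
                    raise ConfigError(f"cohort effect references unknown variable {v!r}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class TruthBundle:
    """Everything needed for parameter-recovery assertions."""

    config: ScenarioConfig
    climate_seasonal: pd.DataFrame      # year x variable, realized seasonal values
    climate_z: pd.DataFrame             # year x variable, standardized
    cohort_means: pd.DataFrame          # year x cohort index, realized mean day
    season_totals: dict[int, int]
    juv_per50: dict[int, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "climate_seasonal": self.climate_seasonal.to_dict(),
            "cohort_means": self.cohort_means.to_dict(),
            "season_totals": {str(k): v for k, v in self.season_totals.items()},
            "juv_per50": {str(k): v for k, v in self.juv_per50.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _config_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["window"] = {"label": config.window.label, "start": config.window.start,
                   "end": config.window.end}
    return d


_WINDOW_CYCLE = [(APR_MAY, 0), (AUG_OCT, 1), (NOV_MAR, 0), (JUN_JUL, 1)]


def synthetic_roster(names: list[str]) -> tuple[VariableSpec, ...]:
    """One VariableSpec per synthetic variable, cycling through the real
    window/lag shapes so the straddle and lag code paths get exercised."""
    specs = []
    for i, name in enumerate(names):
        months, lag = _WINDOW_CYCLE[i % len(_WINDOW_CYCLE)]
        specs.append(VariableSpec(name=name, source=name, months=months, lag_years=lag))
    return tuple(specs)


def gen_climate(
    config: ScenarioConfig,
) -> tuple[dict[str, ClimateSeries], pd.DataFrame]:
    """Generate monthly series whose seasonal means equal the drawn values.

    Every month of a variable's seasonal window is set to the same drawn
    value, so the seasonal mean recovered downstream matches the truth
    exactly.  Returns the series map and the year x variable truth frame.
    """
    roster = synthetic_roster(list(config.climate))
    series_map: dict[str, ClimateSeries] = {}
    truth = {}
    for spec in roster:
        cs = ClimateSeries(spec.source)
        cspec = config.climate[spec.name]
        vals = {}
        for year in config.years:
            rng = substream(config.seed, "climate", spec.name, year)
            value = cspec.mean + cspec.trend * (year - config.start_year)
            if cspec.sd > 0:
                value += rng.normal(0.0, cspec.sd)
            vals[year] = value
            straddle = 12 in spec.months and 1 in spec.months
            for m in spec.months:
                obs_year = year - spec.lag_years - (1 if straddle and m >= 11 else 0)
                cs.observations[(obs_year, m)] = value
        series_map[spec.source] = cs
        truth[spec.name] = vals
    truth_frame = pd.DataFrame(truth, index=pd.Index(config.years, name="year"))
    # sanity: the ingestion path reproduces the drawn seasonal values
    for spec in roster:
        got = seasonal_mean(series_map[spec.source], spec.months, spec.lag_years, config.years[0])
        assert abs(got - truth_frame.loc[config.years[0], spec.name]) < 1e-9
    return series_map, truth_frame


def _standardize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    return (frame - frame.mean()) / frame.std(ddof=1)


def expected_density(
    config: ScenarioConfig, cohort_means: list[float]
) -> np.ndarray:
    """Window-truncated, renormalized mixture density over day indices."""
    days = np.arange(config.window.n_days())
    dens = np.zeros_like(days, dtype=float)
    for c, mu in zip(config.cohorts, cohort_means):
        dens += c.weight * stats.norm.pdf(days, mu, c.sd_days)
    total = dens.sum()
    if total <= 0:
        raise ConfigError("mixture density has no mass inside the window")
    inside = 1.0 - sum(
        c.weight
        * (stats.norm.cdf(-0.5, mu, c.sd_days) + stats.norm.sf(len(days) - 0.5, mu, c.sd_days))
        for c, mu in zip(config.cohorts, cohort_means)
    )
    if inside < 1.0 - config.max_truncated_mass:
        warnings.warn(
            f"{100 * (1 - inside):.1f}% of cohort mass falls outside the window "
            "(truncation bias)", stacklevel=2,
        )
    return dens / total


def _cohort_means_for_year(
    config: ScenarioConfig,
    z_row: pd.Series,
    year: int,
    juv_z: float = 0.0,
) -> list[float]:
    idx = year - config.start_year
    means = []
    for c in config.cohorts:
        mu = c.base_mean_day + c.trend_days_per_year * idx
        mu += sum(eff * z_row[v] for v, eff in c.effects.items())
        mu += config.juvenile_effect_days_per_sd * juv_z
        means.append(mu)
    return means


def gen_passage(
    config: ScenarioConfig,
    z_row: pd.Series,
    year: int,
    total: int | None = None,
    juv_z: float = 0.0,
) -> tuple[SeasonCounts, list[float]]:
    """Multinomial daily counts for one year; returns realized cohort means."""
    means = _cohort_means_for_year(config, z_row, year, juv_z)
    probs = expected_density(config, means)
    if total is None:
        total = _draw_total(config, year)
    rng = substream(config.seed, "passage", year)
    counts = rng.multinomial(int(total), probs)
    return SeasonCounts(year=year, window=config.window, counts=[int(c) for c in counts]), means


def _draw_total(config: ScenarioConfig, year: int) -> int:
    if year in config.low_count_years:
        return int(config.low_count_years[year])
    rng = substream(config.seed, "total", year)
    mean = config.season_total_mean
    if config.season_total_dispersion:
        size = config.season_total_dispersion
        lam = rng.gamma(size, mean / size)
        return max(1, int(rng.poisson(lam)))
    return max(1, int(rng.poisson(mean)))


def gen_study(config: ScenarioConfig, outdir: str | Path) -> TruthBundle:
    """Write captures.csv, effort.csv, climate/monthly.csv and truth.json.

    Output formats match :mod:`phenanom.ringing` and :mod:`phenanom.climate`
    exactly.  A ``recapture_fraction`` of spring birds receives a second
    same-season capture row to exercise first-capture deduplication.
    """
    outdir = Path(outdir)
    (outdir / "climate").mkdir(parents=True, exist_ok=True)

    series_map, truth_frame = gen_climate(config)
    z = _standardize_frame(truth_frame) if len(truth_frame.columns) else truth_frame

    # autumn juvenile counts (year = autumn calendar year), one season
    # before each spring plus the final study autumn
    autumn_years = list(range(config.start_year - 1, config.start_year + config.n_years))
    juv_totals: dict[int, int] = {}
    nets: dict[int, int] = {}
    for ay in autumn_years:
        rng = substream(config.seed, "autumn", ay)
        juv_totals[ay] = max(0, int(round(rng.normal(config.autumn_juv_mean, config.autumn_juv_sd))))
        nets[ay] = int(rng.integers(config.autumn_nets_range[0], config.autumn_nets_range[1] + 1))
    per50 = {ay: juv_totals[ay] / nets[ay] * 50.0 for ay in autumn_years}
    sq = pd.Series({ay: np.sqrt(v) for ay, v in per50.items()})
    juv_z_series = (sq - sq.mean()) / sq.std(ddof=1) if config.juvenile_effect_days_per_sd else sq * 0.0

    capture_rows: list[dict] = []
    cohort_means: dict[int, list[float]] = {}
    season_totals: dict[int, int] = {}

    for year in config.years:
        season, means = gen_passage(
            config, z.loc[year] if len(z.columns) else pd.Series(dtype=float),
            year, juv_z=float(juv_z_series.get(year - 1, 0.0)),
        )
        cohort_means[year] = means
        season_totals[year] = season.total
        dates = config.window.dates(year)
        rng = substream(config.seed, "recapture", year)
        bird = 0
        for day_idx, count in enumerate(season.counts):
            for _ in range(count):
                ring_id = f"S{year}N{bird:05d}"
                bird += 1
                capture_rows.append(
                    {"ring_id": ring_id, "date": dates[day_idx].isoformat(),
                     "age_class": "full_grown", "site": "synthsite"}
                )
                days_left = len(dates) - day_idx - 1
                if days_left > 0 and rng.random() < config.recapture_fraction:
                    redate = dates[day_idx + int(rng.integers(1, days_left + 1))]
                    capture_rows.append(
                        {"ring_id": ring_id, "date": redate.isoformat(),
                         "age_class": "full_grown", "site": "synthsite"}
                    )

    for ay in autumn_years:
        rng = substream(config.seed, "autumn_days", ay)
        dates = AUTUMN.dates(ay)
        day_choices = rng.integers(0, len(dates), size=juv_totals[ay])
        for j, d in enumerate(np.sort(day_choices)):
            capture_rows.append(
                {"ring_id": f"A{ay}N{j:05d}", "date": dates[int(d)].isoformat(),
                 "age_class": "juvenile", "site": "synthsite"}
            )

    captures = pd.DataFrame(capture_rows, columns=["ring_id", "date", "age_class", "site"])
    captures.to_csv(outdir / "captures.csv", index=False)

    effort_rows = [
        {"year": y, "season": "spring", "nets": config.spring_nets} for y in config.years
    ] + [{"year": ay, "season": "autumn", "nets": nets[ay]} for ay in autumn_years]
    pd.DataFrame(effort_rows).to_csv(outdir / "effort.csv", index=False)

    monthly_rows = [
        {"index_name": name, "year": ym[0], "month": ym[1], "value": val}
        for name, series in series_map.items()
        for ym, val in sorted(series.observations.items())
    ]
    pd.DataFrame(monthly_rows, columns=["index_name", "year", "month", "value"]).to_csv(
        outdir / "climate" / "monthly.csv", index=False
    )

    bundle = TruthBundle(
        config=config,
        climate_seasonal=truth_frame,
        climate_z=z,
        cohort_means=pd.DataFrame.from_dict(cohort_means, orient="index"),
        season_totals=season_totals,
        juv_per50=per50,
    )
    bundle.to_json(outdir / "truth.json")
    return bundle
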