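"""End-to-end orchestration: captures → anomalies → models → tables.

These functions are the programmatic core behind the CLI; they return
in-memory results and optionally write tidy CSVs stamped with the run's
config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import anomaly as an
from . import climate as cl
from . import models as md
from . import ringing as ri
from .errors import MissingDataError
from .juveniles import JuvenileRegression, juvenile_regression

__all__ = [
    "RunConfig",
    "AnomalyResult",
    "ModelResult",
    "run_anomaly",
    "juvenile_index_from_captures",
    "run_models",
    "write_stamped_csv",
]


@dataclass
class RunConfig:
    """Serializable parameters of a full pipeline run."""

    captures: str = "captures.csv"
    effort: str = "effort.csv"
    climate_dir: str = "climate"
    recoveries: str | None = None
    out_dir: str = "out"
    years: tuple[int, int] = (1982, 2017)
    min_total: int = 30
    delta_aicc: float = 2.0
    r_threshold: float = 0.7
    sign: int = 1
    exclude_autumn_years: tuple[int, ...] = (1982,)
    candidates: tuple[str, ...] = tuple(s.name for s in cl.DEFAULT_ROSTER) + ("Year",)
    profile_variables: tuple[str, ...] = cl.CORE_NINE
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnomalyResult:
    included: list[ri.SeasonCounts]
    excluded_years: list[int]
    baseline: an.CumCurve
    curves: list[an.CumCurve]
    periods: list[an.PeriodSpec]          # AA + MP1-MP3 + SP1-SP9
    anomalies: pd.DataFrame               # long: year, period, aa_days

    def series(self, period: str) -> pd.Series:
        sub = self.anomalies[self.anomalies["period"] == period]
        return pd.Series(sub["aa_days"].values, index=sub["year"].values, dtype=float)


@dataclass
class ModelResult:
    best: dict[str, md.RegressionFit]
    top: dict[str, list[md.RegressionFit]]
    contributions: dict[str, dict[str, float]]
    trends: list[md.TrendResult]
    profile: md.WindowProfile | None
    juvenile: list[JuvenileRegression] = field(default_factory=list)


def run_anomaly(
    records: list[ri.CaptureRecord],
    years: tuple[int, int],
    min_total: int = 30,
    sign: int = 1,
    window: ri.SeasonWindow = ri.SPRING,
) -> AnomalyResult:
    """Daily counts → filtered seasons → baseline → period anomalies."""
    seasons = []
    for year in range(years[0], years[1] + 1):
        dedup = ri.first_captures(records, window, year)
        seasons.append(ri.daily_counts(dedup, window, year))
    included, excluded = ri.filter_seasons(seasons, min_total=min_total)
    curves = [an.cumulative_percent(s) for s in included]
    baseline = an.multiyear_baseline(curves)
    periods = (
        an.build_periods(baseline, [an.FULL_RANGE], mode="partition")
        + an.build_periods(baseline, an.MAIN_PERIOD_RANGES, mode="partition")
        + an.build_periods(baseline, an.SUB_PERIOD_RANGES, mode="overlap")
    )
    table = an.anomaly_table(curves, baseline, periods, sign=sign)
    return AnomalyResult(
        included=included,
        excluded_years=excluded,
        baseline=baseline,
        curves=curves,
        periods=periods,
        anomalies=table,
    )


def juvenile_index_from_captures(
    records: list[ri.CaptureRecord],
    effort: pd.DataFrame,
    years: tuple[int, int],
) -> dict[int, ri.EffortIndex]:
    """Per-autumn effort-normalized juvenile counts from raw captures."""
    autumn_nets = {
        int(r.year): int(r.nets)
        for r in effort.itertuples(index=False)
        if str(r.season).lower() == "autumn"
    }
    out: dict[int, ri.EffortIndex] = {}
    for year in range(years[0], years[1] + 1):
        if year not in autumn_nets:
            continue
        dedup = ri.first_captures(records, ri.AUTUMN, year)
        juv = sum(1 for r in dedup if r.age_class == ri.AgeClass.JUVENILE)
        out[year] = ri.EffortIndex(year=year, juvenile_total=juv, nets=autumn_nets[year])
    return out


def run_models(
    anomaly_result: AnomalyResult,
    covariates: pd.DataFrame,
    config: RunConfig,
    juvenile_per50: dict[int, float] | None = None,
    main_labels: tuple[str, ...] = ("MP1", "MP2", "MP3", "AA"),
    sub_labels: tuple[str, ...] = tuple(r[0] for r in an.SUB_PERIOD_RANGES),
) -> ModelResult:
    """All-subsets selection per main period, trends, profile, juveniles.

    Years present in the anomaly table but missing any covariate are dropped
    listwise; a :class:`MissingDataError` is raised if nothing remains.
    """
    cand = [c for c in config.candidates if c in covariates.columns]

    best: dict[str, md.RegressionFit] = {}
    top: dict[str, list[md.RegressionFit]] = {}
    contrib: dict[str, dict[str, float]] = {}
    for label in main_labels:
        y_raw = anomaly_result.series(label)
        common = y_raw.index.intersection(covariates.index)
        if len(common) < 5:
            raise MissingDataError(
                f"{label}: only {len(common)} years align with covariates"
            )
        y = cl.standardize(y_raw.loc[common])
        X = cl.standardize_frame(covariates.loc[common, cand])
        fits = md.all_subsets(y, X, cand, response=label)
        best[label] = fits[0]
        top[label] = md.top_models(fits, config.delta_aicc)
        contrib[label] = {c: md.contribution(c, top[label]) for c in cand}

    trends = md.trend_with_bh(
        {lab: anomaly_result.series(lab) for lab in main_labels},
        family=list(main_labels),
    )

    profile = None
    prof_vars = [v for v in config.profile_variables if v in covariates.columns]
    if not prof_vars:
        # none of the configured roster is present (e.g. a synthetic study):
        # profile every non-Year candidate instead
        prof_vars = [c for c in cand if c != "Year"]
    if prof_vars:
        any_y = anomaly_result.series(sub_labels[0])
        common = any_y.index.intersection(covariates.index)
        Xp = cl.standardize_frame(covariates.loc[common, prof_vars])
        profile = md.window_profile(
            {lab: anomaly_result.series(lab).loc[common] for lab in sub_labels},
            Xp,
            variables=prof_vars,
        )

    juv_regs: list[JuvenileRegression] = []
    if juvenile_per50:
        raw_p = []
        for label in main_labels:
            juv_regs.append(
                juvenile_regression(
                    anomaly_result.series(label),
                    juvenile_per50,
                    exclude_autumn_years=config.exclude_autumn_years,
                    period=label,
                )
            )
            raw_p.append(juv_regs[-1].p_raw)

    return ModelResult(
        best=best, top=top, contributions=contrib,
        trends=trends, profile=profile, juvenile=juv_regs,
    )


def write_stamped_csv(frame: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a leading ``# config=<hash>`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        frame.to_csv(fh, index=False)
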