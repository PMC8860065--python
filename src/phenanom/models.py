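"""All-subsets OLS with AICc ranking, partial correlations, VIF, trends.

The selection machinery ranks every subset of a candidate predictor list by
small-sample-corrected AIC, extracts the top-model set (delta AICc below a
cutoff), scores per-variable contributions across that set, and profiles
partial correlations of a fixed predictor roster across the nine
overlapping sub-period anomaly series.

Two independent routes exist for partial correlations: the fit itself
carries ``pR`` derived from the t statistic (pR = t / sqrt(t^2 + df)),
while :func:`partial_correlations` recomputes them from residual-on-residual
Pearson correlations; tests assert the two agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, SingularFitError

__all__ = [
    "RegressionFit",
    "TrendResult",
    "WindowProfile",
    "ols_fit",
    "all_subsets",
    "top_models",
    "contribution",
    "partial_correlations",
    "vif",
    "bh_adjust",
    "trend_with_bh",
    "window_profile",
]


@dataclass
class RegressionFit:
    """One Gaussian OLS fit (with intercept) and its selection statistics."""

    response: str
    predictors: tuple[str, ...]
    n: int
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r2: float
    adj_r2: float
    rss: float
    loglik: float
    aicc: float
    vif: dict[str, float]
    pR: dict[str, float]
    delta_aicc: float = float("nan")

    @property
    def partial_r2(self) -> dict[str, float]:
        return {k: v * v for k, v in self.pR.items()}

    @property
    def k_params(self) -> int:
        """AICc parameter count: predictors + intercept + residual variance."""
        return len(self.predictors) + 2


@dataclass
class TrendResult:
    response: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_raw: float
    p_bh: float
    first_year: int
    last_year: int

    @property
    def total_shift(self) -> float:
        """|fitted endpoint difference| across the observed span, in days."""
        return abs(self.slope) * (self.last_year - self.first_year)


@dataclass
class WindowProfile:
    """Sign-inverted partial correlations across sub-period windows."""

    matrix: pd.DataFrame  # rows: sub-periods, columns: variables, entries: -pR
    fits: dict[str, RegressionFit] = field(default_factory=dict)

    def long_table(self) -> pd.DataFrame:
        long = self.matrix.reset_index(names="period").melt(
            id_vars="period", var_name="variable", value_name="neg_pR"
        )
        return long


def _align(y: pd.Series, X: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    if not y.index.equals(X.index):
        common = y.index.intersection(X.index)
        if len(common) == 0:
            raise DomainError("response and covariates share no years")
        y, X = y.loc[common], X.loc[common]
    return np.asarray(y, dtype=float), X


def ols_fit(
    y: pd.Series,
    X: pd.DataFrame,
    predictor_subset: tuple[str, ...] | list[str] = (),
    response: str = "y",
) -> RegressionFit:
    """OLS of ``y`` on an intercept plus the named columns of ``X``.

    AICc uses the Gaussian maximum-likelihood variance (RSS/n) and counts
    k = p + 2 parameters (intercept and residual variance included):
    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1).
    """
    subset = tuple(predictor_subset)
    yv, X = _align(y, X)
    n = len(yv)
    p = len(subset)
    if n <= p + 2:
        raise DomainError(f"n={n} too small for {p} predictors")
    design = np.column_stack([np.ones(n)] + [np.asarray(X[c], dtype=float) for c in subset])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularFitError(subset)
    beta, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss <= 0:
        raise DomainError("response has zero variance")
    r2 = 1.0 - rss / tss
    dof = n - p - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof

    # Gaussian profile log-likelihood at the MLE variance.
    if rss <= 1e-300:
        loglik = float("inf")
        aicc = float("-inf")
    else:
        loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
        k = p + 2
        if n - k - 1 <= 0:
            aicc = float("inf")
        else:
            aicc = -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    sigma2 = rss / dof if dof > 0 else float("nan")
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof) if dof > 0 else np.full(len(beta), np.nan)

    pr: dict[str, float] = {}
    for i, name in enumerate(subset, start=1):
        t = tvals[i]
        if np.isinf(t):
            pr[name] = float(np.sign(t))
        else:
            pr[name] = float(t / np.sqrt(t * t + dof))

    return RegressionFit(
        response=response,
        predictors=subset,
        n=n,
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(subset, beta[1:])},
        std_errors={c: float(s) for c, s in zip(subset, se[1:])},
        t_values={c: float(t) for c, t in zip(subset, tvals[1:])},
        p_values={c: float(pv) for c, pv in zip(subset, pvals[1:])},
        r2=r2,
        adj_r2=adj_r2,
        rss=rss,
        loglik=loglik,
        aicc=aicc,
        vif=vif(X, subset),
        pR=pr,
    )


def all_subsets(
    y: pd.Series,
    X: pd.DataFrame,
    candidates: list[str],
    response: str = "y",
) -> list[RegressionFit]:
    """Fit every subset of ``candidates`` (including empty); rank by AICc.

    Subsets are enumerated by binary counting over the candidate order, so
    the fit log is deterministic.  Rank-deficient subsets are skipped with a
    warning.  Ties in AICc (within 1e-9) favour fewer predictors, then
    lexicographic predictor names.
    """
    if len(candidates) > 16:
        raise DomainError("more than 16 candidates: all-subsets enumeration refused")
    fits: list[RegressionFit] = []
    for mask in range(1 << len(candidates)):
        subset = tuple(c for j, c in enumerate(candidates) if mask >> j & 1)
        try:
            fits.append(ols_fit(y, X, subset, response=response))
        except SingularFitError as exc:
            warnings.warn(f"skipping singular subset {subset}: {exc}", stacklevel=2)
    fits.sort(key=lambda f: (round(f.aicc / 1e-9) if np.isfinite(f.aicc) else f.aicc,
                             len(f.predictors), f.predictors))
    best = fits[0].aicc
    for f in fits:
        f.delta_aicc = f.aicc - best
    return fits


def top_models(fits: list[RegressionFit], delta_max: float = 2.0) -> list[RegressionFit]:
    """Fits with delta AICc strictly below ``delta_max``."""
    return [f for f in fits if f.delta_aicc < delta_max]


def contribution(
    variable: str, top: list[RegressionFit], method: str = "presence"
) -> float:
    """Importance of ``variable`` across the top-model set.

    ``presence``: fraction of top models containing the variable (default).
    ``akaike``: Akaike-weight sum over top models containing it.
    """
    if not top:
        raise DomainError("top-model set is empty")
    if method == "presence":
        return sum(variable in f.predictors for f in top) / len(top)
    if method == "akaike":
        deltas = np.array([f.delta_aicc for f in top])
        w = np.exp(-0.5 * deltas)
        w /= w.sum()
        return float(sum(wi for wi, f in zip(w, top) if variable in f.predictors))
    raise DomainError(f"unknown contribution method {method!r}")


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(controls, v, rcond=None)
    return v - controls @ beta


def partial_correlations(
    y: pd.Series, X: pd.DataFrame, predictors: tuple[str, ...] | list[str]
) -> dict[str, float]:
    """Residual-on-residual partial correlations.

    For each predictor x_i: regress y and x_i on an intercept plus the
    remaining predictors, then Pearson-correlate the two residual vectors.
    """
    predictors = tuple(predictors)
    if not predictors:
        raise DomainError("need at least one predictor")
    yv, X = _align(y, X)
    n = len(yv)
    out: dict[str, float] = {}
    for name in predictors:
        others = [o for o in predictors if o != name]
        controls = np.column_stack(
            [np.ones(n)] + [np.asarray(X[o], dtype=float) for o in others]
        )
        ry = _residualize(yv, controls)
        rx = _residualize(np.asarray(X[name], dtype=float), controls)
        sy, sx = float(np.std(ry)), float(np.std(rx))
        if sy <= 1e-14 * max(1.0, float(np.std(yv))) or sx <= 1e-14:
            raise DomainError(f"degenerate residuals for predictor {name!r}")
        out[name] = float(np.corrcoef(ry, rx)[0, 1])
    return out


def vif(X: pd.DataFrame, subset: tuple[str, ...] | list[str]) -> dict[str, float]:
    """Variance inflation factors 1/(1 - R2_i) via the correlation inverse.

    A single predictor has VIF exactly 1; perfect collinearity yields inf.
    """
    subset = tuple(subset)
    if not subset:
        return {}
    if len(subset) == 1:
        return {subset[0]: 1.0}
    corr = np.corrcoef(np.asarray(X[list(subset)], dtype=float), rowvar=False)
    try:
        inv = np.linalg.inv(corr)
        diag = np.diag(inv)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError
        return {name: float(d) for name, d in zip(subset, diag)}
    except np.linalg.LinAlgError:
        return {name: float("inf") for name in subset}


def bh_adjust(p_raw: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    if not p_raw:
        return []
    _, p_bh, _, _ = multipletests(p_raw, method="fdr_bh")
    return [float(p) for p in p_bh]


def trend_with_bh(
    anomaly_series: dict[str, dict[int, float] | pd.Series],
    family: list[str] | None = None,
) -> list[TrendResult]:
    """Per-period OLS on calendar year, BH-corrected across the family.

    ``family`` names the periods whose raw p-values form one multiple-testing
    family (defaults to all keys, in insertion order).
    """
    family = list(family) if family is not None else list(anomaly_series)
    partial: list[TrendResult] = []
    for label in family:
        s = pd.Series(anomaly_series[label], dtype=float).sort_index()
        if len(s) < 3:
            raise DomainError(f"trend for {label!r} needs >= 3 years, got {len(s)}")
        years = np.asarray(s.index, dtype=float)
        lr = stats.linregress(years, np.asarray(s, dtype=float))
        partial.append(
            TrendResult(
                response=label,
                n=len(s),
                slope=float(lr.slope),
                intercept=float(lr.intercept),
                r2=float(lr.rvalue**2),
                p_raw=float(lr.pvalue),
                p_bh=float("nan"),
                first_year=int(s.index.min()),
                last_year=int(s.index.max()),
            )
        )
    adjusted = bh_adjust([t.p_raw for t in partial])
    for t, p in zip(partial, adjusted):
        t.p_bh = p
    return partial


def window_profile(
    sub_anomalies: dict[str, dict[int, float] | pd.Series],
    X: pd.DataFrame,
    variables: list[str] | tuple[str, ...] | None = None,
    standardize_response: bool = True,
) -> WindowProfile:
    """Full-roster fits per sub-period; stores sign-inverted pR (−pR).

    Every sub-period anomaly series is regressed on the complete variable
    roster (no subset selection), and the per-variable partial correlations
    are recorded with inverted sign so that a positive profile value means a
    negative correlation (earlier passage with a higher index).
    """
    variables = list(variables) if variables is not None else list(X.columns)
    rows = {}
    fits = {}
    for label, series in sub_anomalies.items():
        y = pd.Series(series, dtype=float).sort_index()
        if standardize_response:
            sd = y.std(ddof=1)
            if sd <= 0:
                raise DomainError(f"zero-variance response {label!r}")
            y = (y - y.mean()) / sd
        fit = ols_fit(y, X, tuple(variables), response=label)
        fits[label] = fit
        rows[label] = {v: -fit.pR[v] for v in variables}
    matrix = pd.DataFrame.from_dict(rows, orient="index")[variables]
    matrix.index.name = "period"
    return WindowProfile(matrix=matrix, fits=fits)
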