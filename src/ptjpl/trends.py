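"""Annual aggregation, OLS trends, broken-stick turning points and
per-pixel correlation maps with significance masking.

Trends are least-squares slopes of annual values against the year, with a
two-sided t-test on the slope. Turning points use a continuous piecewise-
linear ("broken-stick") model

    y = β0 + β1·t + ε            for t ≤ a
    y = β0 + β1·t + β2·(t−a) + ε for t > a

fitted by exhaustive search over admissible integer break years a, choosing
the a that minimizes the residual sum of squares; the trend change is
accepted when β2 is significant at 0.05. Correlation maps are per-pixel
Pearson R on annual series, with pixels masked where p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats


# Variables accumulated to annual totals; everything else is averaged.
SUM_VARIABLES = {"ET", "ET_c", "ET_s", "ET_i", "Pre"}


def annual_aggregate(
    data: xr.Dataset | xr.DataArray | pd.Series,
    statistic: str | dict | None = None,
    allow_partial: bool = False,
):
    """Aggregate a daily cube or series to annual values.

    ``statistic`` is "sum", "mean", a per-variable mapping, or None to use
    the convention: flux-like fields (ET components, precipitation) are
    summed to mm/year, state-like fields (Tm, Rh, NDVI, ...) are averaged.
    Partial calendar years raise unless ``allow_partial`` is set.
    """
    if isinstance(data, pd.Series):
        idx = pd.DatetimeIndex(data.index)
        counts = data.groupby(idx.year).count()
        _check_complete(counts, allow_partial)
        grouped = data.groupby(idx.year)
        out = grouped.sum() if statistic == "sum" else grouped.mean()
        out.index.name = "year"
        return out

    times = pd.DatetimeIndex(np.atleast_1d(data["time"].values))
    counts = pd.Series(1, index=times).groupby(times.year).count()
    _check_complete(counts, allow_partial)

    if isinstance(data, xr.DataArray):
        how = statistic or ("sum" if data.name in SUM_VARIABLES else "mean")
        grouped = data.groupby("time.year")
        return grouped.sum("time") if how == "sum" else grouped.mean("time")

    out = {}
    for name in data.data_vars:
        if isinstance(statistic, dict):
            how = statistic.get(name, "mean")
        elif statistic in ("sum", "mean"):
            how = statistic
        else:
            how = "sum" if name in SUM_VARIABLES else "mean"
        grouped = data[name].groupby("time.year")
        out[name] = grouped.sum("time") if how == "sum" else grouped.mean("time")
    return xr.Dataset(out)


def _check_complete(counts: pd.Series, allow_partial: bool) -> None:
    for year, n in counts.items():
        expected = 366 if pd.Timestamp(year=int(year), month=1, day=1).is_leap_year else 365
        if n != expected and not allow_partial:
            raise ValueError(
                f"partial calendar year {year}: {n} of {expected} days "
                "(pass allow_partial=True to aggregate anyway)"
            )


@dataclass(frozen=True)
class TrendResult:
    """Linear trend of an annual series."""

    slope: float       # units per year
    intercept: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("trend requires n >= 3")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def ols_trend(series: pd.Series) -> TrendResult:
    """Least-squares trend of annual values against the year.

    The p-value is a two-sided t-test on the slope. A constant series has
    slope 0 with p = 1 (no evidence of trend); a constant *regressor*
    (all years equal) is an error.
    """
    y = np.asarray(series.values, dtype=float)
    t = np.asarray(series.index, dtype=float)
    if y.size < 3:
        raise ValueError("ols_trend requires n >= 3")
    if np.ptp(t) == 0:
        raise ValueError("constant regressor: all years identical")
    if np.ptp(y) == 0:
        return TrendResult(slope=0.0, intercept=float(y[0]), p_value=1.0, n=y.size)
    fit = stats.linregress(t, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=y.size,
    )


@dataclass(frozen=True)
class TurningPoint:
    """Broken-stick fit: break year a, coefficients and fit diagnostics."""

    a: int
    beta0: float
    beta1: float
    beta2: float
    p_beta2: float
    sse: float
    sse_linear: float

    @property
    def significant(self) -> bool:
        return self.p_beta2 < 0.05

    def __post_init__(self) -> None:
        if self.sse > self.sse_linear + 1e-9 * max(1.0, self.sse_linear):
            raise ValueError("broken-stick SSE cannot exceed single-line SSE")


def _piecewise_design(t: np.ndarray, a: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - a, 0.0)])


def fit_turning_point(series: pd.Series, edge_exclusion: int = 3) -> TurningPoint:
    """Detect a trend turning point by exhaustive broken-stick search.

    Candidate break years exclude the first and last ``edge_exclusion``
    years of the span (guaranteeing at least three points per segment);
    for each candidate the continuous two-segment model is fitted by least
    squares and the candidate with minimum SSE wins. β2 — the change in
    slope at the break — gets a two-sided t-test (df = n − 3).
    """
    y = np.asarray(series.values, dtype=float)
    years = np.asarray(series.index, dtype=int)
    n = y.size
    if n < 2 * edge_exclusion + 1 or n < 7:
        raise ValueError("series too short for turning-point detection (need n >= 7)")
    t = years.astype(float)

    candidates = years[edge_exclusion:n - edge_exclusion]
    best = None
    for a in candidates:
        X = _piecewise_design(t, float(a))
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, int(a), coef, X)
    sse, a, coef, X = best

    line = np.polyfit(t, y, 1)
    resid_line = y - np.polyval(line, t)
    sse_line = float(resid_line @ resid_line)

    # β2 significance from the standard OLS covariance at the chosen break.
    # An exactly-linear input leaves only rounding noise in both residuals,
    # so the t-statistic would be 0/0 garbage: report β2 as not significant.
    df = n - 3
    scale = max(1.0, float(y @ y))
    if sse_line <= 1e-16 * scale:
        p_b2 = 1.0
    else:
        sigma2 = sse / df if df > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        se_b2 = float(np.sqrt(sigma2 * xtx_inv[2, 2]))
        if se_b2 > 0 and np.isfinite(se_b2):
            t_b2 = coef[2] / se_b2
            p_b2 = float(2.0 * stats.t.sf(abs(t_b2), df))
        else:
            p_b2 = 0.0 if abs(coef[2]) > 1e-9 * np.sqrt(scale) else 1.0

    return TurningPoint(
        a=a,
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        p_beta2=p_b2,
        sse=min(sse, sse_line),  # guard float jitter in the nested-model bound
        sse_linear=sse_line,
    )


def trend_map(annual: xr.DataArray) -> xr.Dataset:
    """Per-pixel OLS trend of an annual cube: slope and p-value bands."""
    years = np.asarray(annual["year"].values, dtype=float)
    vals = annual.transpose("year", ...).values
    nt = vals.shape[0]
    flat = vals.reshape(nt, -1)
    tc = years - years.mean()
    sxx = float(tc @ tc)
    yc = flat - flat.mean(axis=0)
    slope = (tc @ yc) / sxx
    resid = yc - np.outer(tc, slope)
    df = nt - 2
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(se > 0, p, np.where(np.abs(slope) > 0, 0.0, 1.0))
    shape = vals.shape[1:]
    dims = [d for d in annual.dims if d != "year"]
    coords = {d: annual[d] for d in dims}
    return xr.Dataset(
        {
            "slope": (dims, slope.reshape(shape)),
            "p": (dims, p.reshape(shape)),
        },
        coords=coords,
    )


def correlation_map(a: xr.DataArray, b: xr.DataArray, alpha: float = 0.05) -> xr.Dataset:
    """Per-pixel Pearson correlation of two annual cubes.

    Returns R, the two-sided p-value, and a boolean ``masked`` band that is
    True where the correlation is non-significant (p > alpha). Pixels where
    either series has zero variance get R = NaN and are excluded from the
    mask (``valid`` = False).
    """
    if a.sizes != b.sizes:
        raise ValueError("cubes must share shape and coordinates")
    dim = "year" if "year" in a.dims else "time"
    n = a.sizes[dim]
    if n < 3:
        raise ValueError("correlation requires n >= 3 per pixel")
    av = a.transpose(dim, ...).values.reshape(n, -1)
    bv = b.transpose(dim, ...).values.reshape(n, -1)
    ac = av - av.mean(axis=0)
    bc = bv - bv.mean(axis=0)
    sa = np.sqrt((ac ** 2).sum(axis=0))
    sb = np.sqrt((bc ** 2).sum(axis=0))
    # relative threshold: a numerically-constant series (rounding residue
    # only) counts as zero variance
    tol_a = 1e-10 * np.maximum(np.abs(av).max(axis=0), 1e-300)
    tol_b = 1e-10 * np.maximum(np.abs(bv).max(axis=0), 1e-300)
    valid = (sa > tol_a) & (sb > tol_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, (ac * bc).sum(axis=0) / (sa * sb), np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    p = np.where(valid, 2.0 * stats.t.sf(np.abs(tstat), df), np.nan)
    shape = tuple(s for d, s in a.sizes.items() if d != dim)
    dims = [d for d in a.dims if d != dim]
    coords = {d: a[d] for d in dims}
    return xr.Dataset(
        {
            "r": (dims, r.reshape(shape)),
            "p": (dims, p.reshape(shape)),
            "masked": (dims, (np.where(valid, p > alpha, False)).reshape(shape)),
            "valid": (dims, valid.reshape(shape)),
        },
        coords=coords,
    )
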