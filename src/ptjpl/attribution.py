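"""Scenario-controlled attribution of ET change to climate vs. vegetation.

Two kinds of simulation experiment are run: a normal model run (S_ALL)
with all drivers varying, and parameter-controlled runs in which selected
drivers are frozen at an initial baseline annual cycle while the rest vary
(S_NDVI0 holds NDVI; S_CLI0 holds the climate drivers Rn, Tm, Rh). Driver
sensitivities are then the coefficients of an intercept-free linear
regression of the ET differences on the driver differences:

    ΔET(S_ALL − S_NDVI0) = β_NDVI·ΔNDVI + ε
    ΔET(S_ALL − S_CLI0)  = β_Tm·ΔTm + β_Rh·ΔRh + β_Rn·ΔRn + ε

With Gaussian ε the maximum-likelihood point estimates coincide with
ordinary least squares; standard errors use the unbiased residual-variance
estimator. Fits are performed on basin-mean annual series by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import statsmodels.api as sm

from .model import PTJPLParams, compute_et, prepare_forcing
from .trends import annual_aggregate
from .gridio import gap_fill_linear, log

ATTRIBUTABLE_DRIVERS = ("Rn", "Tm", "Rh", "NDVI")
CLIMATE_DRIVERS = ("Rn", "Tm", "Rh")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation experiment: which drivers are frozen at baseline."""

    name: str
    held: frozenset[str] = frozenset()
    baseline_policy: str = "first-year"

    def __post_init__(self) -> None:
        unknown = set(self.held) - set(ATTRIBUTABLE_DRIVERS)
        if unknown:
            raise ValueError(f"unknown driver(s) in scenario {self.name!r}: {sorted(unknown)}")


S_ALL = ScenarioSpec("S_ALL", frozenset())
S_CLI0 = ScenarioSpec("S_CLI0", frozenset(CLIMATE_DRIVERS))
S_NDVI0 = ScenarioSpec("S_NDVI0", frozenset({"NDVI"}))

STANDARD_SCENARIOS = {"S_ALL": S_ALL, "S_CLI0": S_CLI0, "S_NDVI0": S_NDVI0}


def make_baseline(
    forcing: xr.Dataset,
    drivers: set[str] | frozenset[str],
    policy: str = "first-year",
) -> xr.Dataset:
    """Freeze the listed drivers at a repeating baseline annual cycle.

    ``first-year`` (default) repeats the first calendar year's daily cycle
    in every year; ``first-3-climatology`` repeats the day-of-year mean of
    the first three calendar years. Feb 29 maps to Feb 28 in years where
    the baseline lacks it. All other drivers are untouched.

    Composite-cadence drivers (NDVI, with gaps between composite days) are
    gap-filled to daily within the base period before mapping, and the
    target's own missingness pattern is re-imposed afterwards, so the
    frozen driver keeps the cadence downstream gap filling expects.
    """
    drivers = set(drivers)
    if not drivers:
        raise ValueError("drivers must be non-empty")
    unknown = drivers - set(forcing.data_vars)
    if unknown:
        raise ValueError(f"unknown driver(s): {sorted(unknown)}")
    times = pd.DatetimeIndex(forcing["time"].values)
    years = times.year
    if years.max() - years.min() < 1:
        raise ValueError("make_baseline needs a span of at least 2 years")

    if policy == "first-year":
        base_sel = years == years.min()
    elif policy == "first-3-climatology":
        base_sel = years <= years.min() + 2
    else:
        raise ValueError(f"unknown baseline policy {policy!r}")

    key = times.month * 100 + times.day
    base_keys = key[base_sel]

    out = forcing.copy()
    for name in drivers:
        da = forcing[name].transpose("time", ...)
        vals = da.values
        nan_mask = np.isnan(vals)
        base_vals = vals[base_sel]
        if np.isnan(base_vals).any():
            base_vals = gap_fill_linear(base_vals, axis=0)
        # day-of-year lookup table (mean over base years; first-year policy
        # has exactly one sample per (month, day))
        frame = pd.DataFrame(base_vals.reshape(base_vals.shape[0], -1))
        table = frame.groupby(np.asarray(base_keys)).mean()
        lookup = np.asarray(key).copy()
        missing = ~np.isin(lookup, table.index)
        lookup[missing & (lookup == 229)] = 228  # Feb 29 -> Feb 28
        new = table.loc[lookup].to_numpy().reshape(vals.shape)
        new[nan_mask] = np.nan
        out[name] = (da.dims, new, da.attrs)
    return out


@dataclass
class ScenarioRun:
    """Annual basin-mean outputs of one scenario run."""

    name: str
    et_annual: pd.DataFrame        # mm/year: ET, ET_c, ET_s, ET_i
    drivers_annual: pd.DataFrame   # annual-mean Rn, Tm, Rh, NDVI


def run_scenarios(
    forcing: xr.Dataset,
    params: PTJPLParams = PTJPLParams(),
    scenarios: list[ScenarioSpec] | None = None,
) -> dict[str, ScenarioRun]:
    """Run the model under each scenario and aggregate to annual basin means."""
    scenarios = scenarios or [S_ALL, S_CLI0, S_NDVI0]
    if not any(s.name == "S_ALL" for s in scenarios):
        raise ValueError("scenarios must include S_ALL (the normal run)")
    results: dict[str, ScenarioRun] = {}
    for spec in scenarios:
        cube = forcing if not spec.held else make_baseline(
            forcing, spec.held, spec.baseline_policy
        )
        prepared = prepare_forcing(cube, params)
        et = compute_et(prepared, params)
        annual_et = annual_aggregate(et[["ET", "ET_c", "ET_s", "ET_i"]], "sum")
        annual_drivers = annual_aggregate(
            prepared[list(ATTRIBUTABLE_DRIVERS)], "mean"
        )
        results[spec.name] = ScenarioRun(
            name=spec.name,
            et_annual=annual_et.mean(["y", "x"]).to_dataframe()[
                ["ET", "ET_c", "ET_s", "ET_i"]
            ],
            drivers_annual=annual_drivers.mean(["y", "x"]).to_dataframe()[
                list(ATTRIBUTABLE_DRIVERS)
            ],
        )
        log.info("run_scenarios: %s done (held: %s)", spec.name,
                 sorted(spec.held) or "none")
    return results


@dataclass
class AttributionResult:
    """Per-driver sensitivities from the difference regression."""

    table: pd.DataFrame       # index driver; columns beta, se, t, p
    resid_var: float
    n: int
    r_squared: float
    intercept: float | None = None

    def __post_init__(self) -> None:
        if (self.table["se"] < 0).any():
            raise ValueError("standard errors must be >= 0")


def fit_attribution(
    delta_et: pd.Series | np.ndarray,
    deltas: pd.DataFrame,
    intercept: bool = False,
) -> AttributionResult:
    """Fit the intercept-free difference regression by Gaussian ML (= OLS).

    Raises on rank-deficient designs (e.g. collinear driver differences or
    an all-zero driver column) and on n ≤ p + 1.
    """
    y = np.asarray(delta_et, dtype=float)
    X = deltas.to_numpy(dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("delta_et and deltas must have equal length")
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} coefficients (need n > p + 1)")
    design = sm.add_constant(X) if intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design: driver differences are collinear or constant"
        )
    fit = sm.OLS(y, design).fit()
    k = 1 if intercept else 0
    table = pd.DataFrame(
        {
            "beta": fit.params[k:],
            "se": fit.bse[k:],
            "t": fit.tvalues[k:],
            "p": fit.pvalues[k:],
        },
        index=list(deltas.columns),
    )
    return AttributionResult(
        table=table,
        resid_var=float(fit.mse_resid),
        n=n,
        r_squared=float(fit.rsquared),
        intercept=float(fit.params[0]) if intercept else None,
    )


def attribute_et(
    forcing: xr.Dataset,
    params: PTJPLParams = PTJPLParams(),
    component: str = "ET",
    intercept: bool = False,
    runs: dict[str, ScenarioRun] | None = None,
) -> dict[str, AttributionResult]:
    """Full attribution pipeline for one ET component.

    Runs S_ALL / S_CLI0 / S_NDVI0, forms annual basin-mean differences and
    fits the vegetation (ΔNDVI) and climate (ΔTm, ΔRh, ΔRn) regressions
    separately, as the two experiment pairs define them.
    """
    if runs is None:
        runs = run_scenarios(forcing, params)
    s_all = runs["S_ALL"]
    out: dict[str, AttributionResult] = {}

    d_et_veg = s_all.et_annual[component] - runs["S_NDVI0"].et_annual[component]
    d_ndvi = (s_all.drivers_annual["NDVI"]
              - runs["S_NDVI0"].drivers_annual["NDVI"]).to_frame("NDVI")
    out["vegetation"] = fit_attribution(d_et_veg, d_ndvi, intercept=intercept)

    d_et_cli = s_all.et_annual[component] - runs["S_CLI0"].et_annual[component]
    d_cli = pd.DataFrame(
        {
            d: s_all.drivers_annual[d] - runs["S_CLI0"].drivers_annual[d]
            for d in ("Tm", "Rh", "Rn")
        }
    )
    out["climate"] = fit_attribution(d_et_cli, d_cli, intercept=intercept)
    return out
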