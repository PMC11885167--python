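"""PT-JPL evapotranspiration model with component partitioning.

Daily actual evapotranspiration is obtained by downscaling Priestley-Taylor
potential evaporation with multiplicative eco-physiological constraints and
splitting it into canopy transpiration (ET_c), soil evaporation (ET_s) and
interception evaporation (ET_i):

    ET   = ET_c + ET_s + ET_i
    ET_c = (1 − f_wet) · f_g · f_T · f_M · α · Δ/(Δ+γ) · R_nc / λ
    ET_s = (f_wet + f_SM (1 − f_wet)) · α · Δ/(Δ+γ) · (R_ns − G) / λ
    ET_i = f_wet · α · Δ/(Δ+γ) · R_nc / λ

Net radiation is partitioned between soil and canopy by the Beer–Lambert
law, R_ns = Rn·exp(−k_Rn·LAI), R_nc = Rn − R_ns; LAI is inverted from NDVI
through f_IPAR = m2·NDVI + b2 and LAI = −ln(1 − f_IPAR)/k_PAR.

The five constraint factors follow the canonical forms of the original
PT-JPL formulation:
f_wet = (Rh/100)^4, f_g = f_APAR/f_IPAR (≤1), f_T = exp(−((Tm−T_opt)/T_opt)²),
f_M = f_APAR/f_APAR,max, f_SM = (Rh/100)^(VPD/β_sm). Negative component
fluxes are clamped at zero before summation (clamp counts logged), so the
additivity and non-negativity invariants hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .gridio import gap_fill_linear, log

REQUIRED_FORCING = ("Rn", "Tm", "Rh", "NDVI")


@dataclass(frozen=True)
class PTJPLParams:
    """Model parameters with their standard literature defaults.

    alpha        Priestley-Taylor coefficient (1.26, unitless).
    gamma        psychrometric constant, kPa/degC.
    k_rn         Beer–Lambert extinction coefficient for net radiation.
    k_par        extinction coefficient for PAR (LAI inversion).
    m2, b2       linear NDVI → f_IPAR coefficients.
    m1, b1       linear NDVI → f_APAR coefficients (defaults equal m2/b2,
                 making f_g = 1; kept separate because the f_APAR pathway
                 is configurable).
    beta_sm      soil-moisture sensitivity of f_SM, kPa.
    t_opt_fallback  constant optimum temperature (degC) used where the
                 per-pixel climatological estimate is degenerate.
    lam          latent heat of vaporization, MJ/kg (1 mm ≡ 2.45 MJ/m2).
    g_fraction   ground heat flux as a fraction of R_ns (0 at daily scale).
    fipar_max    upper clamp on f_IPAR, guarding the log singularity.
    printed_soil_radiation  if True, soil evaporation is driven by R_nc
                 (reproducing a printed variant) instead of R_ns − G.
    """

    alpha: float = 1.26
    gamma: float = 0.066
    k_rn: float = 0.6
    k_par: float = 0.5
    m2: float = 1.0
    b2: float = -0.05
    m1: float = 1.0
    b1: float = -0.05
    beta_sm: float = 1.0
    t_opt_fallback: float = 25.0
    lam: float = 2.45
    g_fraction: float = 0.0
    fipar_max: float = 0.98
    printed_soil_radiation: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "k_rn", "k_par", "lam", "beta_sm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.g_fraction < 1.0:
            raise ValueError("g_fraction must lie in [0, 1)")
        if not 0.0 < self.fipar_max < 1.0:
            raise ValueError("fipar_max must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Thermodynamic primitives (Tetens / FAO-56 forms)
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(tm):
    """Saturation vapor pressure e_sat (kPa) at air temperature tm (degC)."""
    tm = np.asarray(tm, dtype=float)
    return 0.6108 * np.exp(17.27 * tm / (tm + 237.3))


def saturation_slope(tm):
    """Slope Δ of the saturation vapor pressure curve (kPa/degC).

    Analytic derivative of the Tetens form; strictly positive and
    increasing over the physical air-temperature range.
    """
    tm = np.asarray(tm, dtype=float)
    if np.any(tm < -60.0) or np.any(tm > 60.0):
        raise ValueError("tm outside physical range [-60, 60] degC")
    es = saturation_vapor_pressure(tm)
    return 4098.0 * es / (tm + 237.3) ** 2


def vpd_from_tm_rh(tm, rh):
    """Vapor pressure deficit (kPa) from air temperature and relative humidity."""
    rh = np.asarray(rh, dtype=float)
    finite = np.isfinite(rh)
    if np.any((rh[finite] < 0.0) | (rh[finite] > 100.0)):
        raise ValueError("rh outside [0, 100] %")
    return saturation_vapor_pressure(tm) * (1.0 - rh / 100.0)


# ---------------------------------------------------------------------------
# Vegetation radiative structure
# ---------------------------------------------------------------------------

def fipar_from_ndvi(ndvi, params: PTJPLParams = PTJPLParams()):
    """Intercepted-PAR fraction from NDVI, clamped to [0, fipar_max]."""
    ndvi = np.asarray(ndvi, dtype=float)
    finite = np.isfinite(ndvi)
    if np.any((ndvi[finite] < -0.2) | (ndvi[finite] > 1.0)):
        raise ValueError("ndvi outside [-0.2, 1]")
    return np.clip(params.m2 * ndvi + params.b2, 0.0, params.fipar_max)


def fapar_from_ndvi(ndvi, params: PTJPLParams = PTJPLParams()):
    """Absorbed-PAR fraction from NDVI (configurable linear pathway)."""
    ndvi = np.asarray(ndvi, dtype=float)
    return np.clip(params.m1 * ndvi + params.b1, 0.0, 1.0)


def lai_from_fipar(f_ipar, params: PTJPLParams = PTJPLParams()):
    """Leaf area index from f_IPAR by Beer–Lambert inversion."""
    f_ipar = np.asarray(f_ipar, dtype=float)
    finite = np.isfinite(f_ipar)
    if np.any(f_ipar[finite] >= 1.0) or np.any(f_ipar[finite] < 0.0):
        raise ValueError("f_ipar must lie in [0, 1) (log singularity at 1)")
    return -np.log(1.0 - f_ipar) / params.k_par


def partition_net_radiation(rn, lai, params: PTJPLParams = PTJPLParams()):
    """Beer–Lambert split of net radiation: returns (R_ns, R_nc).

    R_ns + R_nc = Rn holds exactly because R_nc is computed as the residual.
    """
    rn = np.asarray(rn, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(lai[np.isfinite(lai)] < 0.0):
        raise ValueError("lai must be >= 0")
    r_ns = rn * np.exp(-params.k_rn * lai)
    return r_ns, rn - r_ns


# ---------------------------------------------------------------------------
# Forcing preparation (gap filling + derived fields)
# ---------------------------------------------------------------------------

def prepare_forcing(forcing: xr.Dataset, params: PTJPLParams = PTJPLParams()) -> xr.Dataset:
    """Gap-fill composite NDVI to daily and add derived VPD, f_IPAR, LAI."""
    for name in REQUIRED_FORCING:
        if name not in forcing:
            raise ValueError(f"forcing cube is missing required field {name!r}")
    out = forcing.copy()
    ndvi = out["NDVI"]
    taxis = ndvi.dims.index("time")
    if bool(np.isnan(ndvi.values).any()):
        out["NDVI"] = (ndvi.dims, gap_fill_linear(ndvi.values, axis=taxis), ndvi.attrs)
    out["VPD"] = (out["Tm"].dims,
                  np.asarray(vpd_from_tm_rh(out["Tm"].values, out["Rh"].values)),
                  {"units": "kPa"})
    f_ipar = fipar_from_ndvi(out["NDVI"].values, params)
    out["fIPAR"] = (out["NDVI"].dims, f_ipar, {"units": "1"})
    out["LAI"] = (out["NDVI"].dims, np.asarray(lai_from_fipar(f_ipar, params)),
                  {"units": "m2 m-2"})
    return out


def optimum_temperature(prepared: xr.Dataset, params: PTJPLParams = PTJPLParams()) -> xr.DataArray:
    """Per-pixel optimum plant temperature T_opt (degC).

    T_opt is the climatological-monthly mean air temperature of the month
    maximizing NDVI·Tm/VPD (phenology-peak heuristic); pixels where the
    estimate is non-positive or undefined fall back to a constant.
    """
    monthly = prepared[["Tm", "NDVI", "VPD"]].groupby("time.month").mean("time")
    index = monthly["NDVI"] * monthly["Tm"] / np.maximum(monthly["VPD"], 0.05)
    best = index.fillna(-np.inf).argmax("month")
    t_opt = monthly["Tm"].isel(month=best).drop_vars("month")
    bad = ~np.isfinite(t_opt) | (t_opt <= 0.0)
    return xr.where(bad, params.t_opt_fallback, t_opt)


# ---------------------------------------------------------------------------
# Constraint factors
# ---------------------------------------------------------------------------

def compute_constraints(forcing: xr.Dataset, params: PTJPLParams = PTJPLParams()) -> xr.Dataset:
    """The five PT-JPL downscaling factors, each in [0, 1], per cell/day."""
    prepared = forcing if "LAI" in forcing else prepare_forcing(forcing, params)

    rh = prepared["Rh"] / 100.0
    f_wet = rh ** 4

    f_apar = xr.DataArray(
        fapar_from_ndvi(prepared["NDVI"].values, params),
        dims=prepared["NDVI"].dims, coords=prepared["NDVI"].coords,
    )
    f_ipar = prepared["fIPAR"]
    f_g = xr.where(f_ipar > 0, np.minimum(f_apar / f_ipar.where(f_ipar > 0), 1.0), 0.0)

    t_opt = optimum_temperature(prepared, params)
    f_t = np.exp(-(((prepared["Tm"] - t_opt) / t_opt) ** 2))

    f_apar_max = f_apar.max("time")
    f_m = xr.where(f_apar_max > 0, np.minimum(f_apar / f_apar_max.where(f_apar_max > 0), 1.0), 0.0)

    f_sm = np.minimum(rh ** (prepared["VPD"] / params.beta_sm), 1.0)

    out = xr.Dataset(
        {"f_wet": f_wet, "f_g": f_g, "f_T": f_t, "f_M": f_m, "f_SM": f_sm}
    )
    for v in out.data_vars:
        out[v] = out[v].clip(0.0, 1.0)
        out[v].attrs["units"] = "1"
    return out


# ---------------------------------------------------------------------------
# Component fluxes
# ---------------------------------------------------------------------------

def et_from_factors(tm, rnc, rns, f_wet, f_g, f_t, f_m, f_sm,
                    params: PTJPLParams = PTJPLParams(), g=0.0):
    """Component fluxes (ET_c, ET_s, ET_i) in mm/day from resolved terms.

    Energy fluxes (MJ/m2/day) are converted to water depth by dividing by
    λ. Each component is clamped at zero; the number of clamped values is
    returned so callers can log it.
    """
    delta = saturation_slope(tm)
    pt = params.alpha * delta / (delta + params.gamma)
    soil_energy = rnc if params.printed_soil_radiation else (np.asarray(rns) - g)
    et_c = (1.0 - np.asarray(f_wet)) * f_g * f_t * f_m * pt * np.asarray(rnc) / params.lam
    et_s = (np.asarray(f_wet) + f_sm * (1.0 - np.asarray(f_wet))) * pt * soil_energy / params.lam
    et_i = np.asarray(f_wet) * pt * np.asarray(rnc) / params.lam
    n_clamped = int(sum(np.sum(np.asarray(c) < 0) for c in (et_c, et_s, et_i)))
    return (np.maximum(et_c, 0.0), np.maximum(et_s, 0.0),
            np.maximum(et_i, 0.0), n_clamped)


def compute_et(
    forcing: xr.Dataset,
    params: PTJPLParams = PTJPLParams(),
    constraints: xr.Dataset | None = None,
) -> xr.Dataset:
    """Run the full PT-JPL partitioned ET model over a forcing cube.

    Returns a dataset with ET, ET_c, ET_s, ET_i (mm/day), the radiation
    partition R_nc, R_ns and ground heat flux G (MJ/m2/day). Additivity
    ET = ET_c + ET_s + ET_i and conservation R_nc + R_ns = Rn are exact.
    """
    prepared = forcing if "LAI" in forcing else prepare_forcing(forcing, params)
    if constraints is None:
        constraints = compute_constraints(prepared, params)
    constraints = constraints.transpose(*prepared["Rn"].dims)

    rn = prepared["Rn"].values
    r_ns, r_nc = partition_net_radiation(rn, prepared["LAI"].values, params)
    g = params.g_fraction * r_ns

    et_c, et_s, et_i, n_clamped = et_from_factors(
        prepared["Tm"].values, r_nc, r_ns,
        constraints["f_wet"].values, constraints["f_g"].values,
        constraints["f_T"].values, constraints["f_M"].values,
        constraints["f_SM"].values, params, g=g,
    )
    if n_clamped:
        log.info("compute_et: clamped %d negative component values to 0", n_clamped)

    dims = prepared["Rn"].dims
    coords = prepared["Rn"].coords
    mm = {"units": "mm day-1"}
    mj = {"units": "MJ m-2 day-1"}
    out = xr.Dataset(
        {
            "ET": (dims, et_c + et_s + et_i, mm),
            "ET_c": (dims, et_c, mm),
            "ET_s": (dims, et_s, mm),
            "ET_i": (dims, et_i, mm),
            "R_nc": (dims, r_nc, mj),
            "R_ns": (dims, r_ns, mj),
            "G": (dims, np.broadcast_to(g, et_c.shape).copy(), mj),
        },
        coords=coords,
        attrs={"n_clamped": n_clamped},
    )
    return out
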