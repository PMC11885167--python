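"""Paired simulation/observation evaluation statistics and the
energy-balance-closure adjustment for flux-tower observations.

Statistics follow their standard definitions: Pearson correlation R,
root-mean-square error, bias = mean(sim) − mean(obs), and Nash–Sutcliffe
efficiency NSE = 1 − Σ(sim−obs)² / Σ(obs−mean(obs))². NSE = 1 is a perfect
simulation; NSE = 0 means the simulation is only as good as the
observation mean; NSE < 0 is worse than the mean.

Eddy-covariance towers typically under-close the surface energy balance
(LE + H < Rn − G). The closure correction rescales the turbulent fluxes by
(Rn − G)/(LE + H), which preserves the Bowen ratio H/LE while forcing
LE_corr + H_corr = Rn − G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ValidationStats:
    """Paired sim/obs evaluation metrics for a daily ET series."""

    r: float
    r_squared: float
    rmse: float      # mm/day
    bias: float      # mm/day
    nse: float
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("R must lie in [-1, 1]")
        if self.rmse < 0:
            raise ValueError("RMSE must be >= 0")
        if np.isfinite(self.nse) and self.nse > 1.0 + 1e-12:
            raise ValueError("NSE cannot exceed 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def report(self) -> str:
        return (
            f"n     = {self.n}\n"
            f"R     = {self.r:.4f}\n"
            f"R^2   = {self.r_squared:.4f}\n"
            f"RMSE  = {self.rmse:.4f} mm/day\n"
            f"bias  = {self.bias:+.4f} mm/day\n"
            f"NSE   = {self.nse:.4f}\n"
        )


def compute_stats(series: pd.DataFrame | None = None,
                  sim=None, obs=None) -> ValidationStats:
    """Evaluation statistics for paired simulated vs. observed daily ET.

    Accepts either a SiteSeries frame with ``et_sim_mm``/``et_obs_mm``
    columns or explicit ``sim``/``obs`` arrays. When the observations have
    zero variance, R and NSE are undefined and reported as NaN.
    """
    if series is not None:
        sim = series["et_sim_mm"].to_numpy(dtype=float)
        obs = series["et_obs_mm"].to_numpy(dtype=float)
    else:
        sim = np.asarray(sim, dtype=float)
        obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValueError("sim and obs must be 1-D arrays of equal length")
    if np.isnan(sim).any() or np.isnan(obs).any():
        raise ValueError("paired series must have no missing values after alignment")
    n = sim.size
    if n < 2:
        raise ValueError("statistics require n >= 2")

    err = sim - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(sim) - np.mean(obs))

    obs_dev = obs - obs.mean()
    sim_dev = sim - sim.mean()
    ss_obs = float(obs_dev @ obs_dev)
    ss_sim = float(sim_dev @ sim_dev)
    if ss_obs == 0.0:
        r = np.nan
        nse = np.nan
    else:
        nse = float(1.0 - (err @ err) / ss_obs)
        r = (
            float((sim_dev @ obs_dev) / np.sqrt(ss_sim * ss_obs))
            if ss_sim > 0.0
            else np.nan
        )
        if np.isfinite(r):
            r = float(np.clip(r, -1.0, 1.0))
    return ValidationStats(
        r=r,
        r_squared=r * r if np.isfinite(r) else np.nan,
        rmse=rmse,
        bias=bias,
        nse=nse,
        n=n,
    )


def energy_closure_correct(le, h, rn, g=0.0, lam: float = 2.45):
    """Bowen-ratio-preserving energy-balance-closure correction.

    Scales daily latent heat by (Rn − G)/(LE + H) so the corrected
    turbulent fluxes close the balance. Records with non-positive
    available energy or turbulent-flux sum cannot be corrected; they come
    back NaN and are counted.

    Returns ``(le_corr, et_corr_mm, n_skipped)`` with LE in the input
    energy units (MJ/m2/day for the default λ to yield mm/day).
    """
    le = np.asarray(le, dtype=float)
    h = np.asarray(h, dtype=float)
    rn = np.asarray(rn, dtype=float)
    g = np.broadcast_to(np.asarray(g, dtype=float), le.shape)
    turbulent = le + h
    available = rn - g
    ok = (turbulent > 0) & (available > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        le_corr = np.where(ok, le * available / turbulent, np.nan)
    n_skipped = int((~ok).sum())
    return le_corr, le_corr / lam, n_skipped


def read_site_csv(path: str | Path) -> pd.DataFrame:
    """Read a SiteSeries CSV (columns date, et_sim_mm, et_obs_mm)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "et_sim_mm", "et_obs_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"site CSV is missing column(s): {sorted(missing)}")
    return df


def write_site_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
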