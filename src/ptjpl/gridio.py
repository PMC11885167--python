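"""Gridded I/O, resampling, gap filling and range QC.

Conventions fixed here and used everywhere else in the package:
north-up grids, row-major storage, cell-center registration, and a daily
calendar time axis (``numpy.datetime64``, no fractional years).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import xarray as xr
import yaml
from scipy.interpolate import RegularGridInterpolator

log = logging.getLogger("ptjpl")

# Physical plausibility bounds used for range QC (per-variable).
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "Rn": (-50.0, 50.0),   # MJ/m2/day
    "Tm": (-60.0, 60.0),   # degC
    "Rh": (0.0, 100.0),    # %
    "Ws": (0.0, 100.0),    # m/s
    "Pre": (0.0, np.inf),  # mm/day
    "NDVI": (-0.2, 1.0),   # unitless
}


@dataclass(frozen=True)
class GridSpec:
    """North-up regular grid, cell-center registered.

    ``origin_x``/``origin_y`` are the coordinates of the *center* of the
    upper-left cell; y decreases down the rows.
    """

    rows: int
    cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("GridSpec rows and cols must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("GridSpec cell_size must be > 0")

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + self.cell_size * np.arange(self.cols)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y - self.cell_size * np.arange(self.rows)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class QCReport:
    """Count of values masked by range QC, per field."""

    field: str
    n_total: int
    n_masked: int

    @property
    def masked_fraction(self) -> float:
        return self.n_masked / self.n_total if self.n_total else 0.0


@dataclass
class RunConfig:
    """Run configuration loaded from a YAML file.

    Sections not interpreted here (forcing, params, scenarios) are kept as
    plain mappings and consumed by the stage that needs them.
    """

    forcing: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=lambda: ["S_ALL", "S_CLI0", "S_NDVI0"])
    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def bilinear_resample(
    values: np.ndarray,
    coarse: GridSpec,
    target: GridSpec,
    edge_clamp: bool = False,
) -> np.ndarray:
    """Bilinearly resample a 2-D field between cell-center registered grids.

    Each target cell-center value is the bilinear combination of the four
    surrounding coarse cell centers; a constant field is reproduced exactly
    and the value at a coarse cell center equals that cell's value.

    Parameters
    ----------
    values
        2-D array of shape ``(coarse.rows, coarse.cols)``.
    edge_clamp
        If True, target points outside the coarse cell-center envelope are
        clamped to the nearest edge instead of raising.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (coarse.rows, coarse.cols):
        raise ValueError(
            f"field shape {values.shape} does not match coarse grid "
            f"({coarse.rows}, {coarse.cols})"
        )
    # RegularGridInterpolator needs ascending axes; flip y (north-up).
    y_asc = coarse.y_centers[::-1]
    interp = RegularGridInterpolator(
        (y_asc, coarse.x_centers),
        values[::-1, :],
        method="linear",
        bounds_error=not edge_clamp,
        fill_value=None,
    )
    ty = target.y_centers
    tx = target.x_centers
    if edge_clamp:
        ty = np.clip(ty, y_asc[0], y_asc[-1])
        tx = np.clip(tx, coarse.x_centers[0], coarse.x_centers[-1])
    else:
        if (
            ty.min() < y_asc[0] - 1e-12
            or ty.max() > y_asc[-1] + 1e-12
            or tx.min() < coarse.x_centers[0] - 1e-12
            or tx.max() > coarse.x_centers[-1] + 1e-12
        ):
            raise ValueError(
                "target grid extends outside the coarse cell-center envelope "
                "(enable edge_clamp to clamp to the edge)"
            )
    yy, xx = np.meshgrid(ty, tx, indexing="ij")
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(
        target.rows, target.cols
    )


# ---------------------------------------------------------------------------
# Composite-to-daily gap filling
# ---------------------------------------------------------------------------

def gap_fill_linear(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fill NaN gaps by linear interpolation along ``axis``.

    Straight-line interpolation between the surrounding valid samples;
    positions before the first / after the last valid sample are held flat.
    This is how composite-cadence vegetation indices (e.g. 16-day NDVI) are
    expanded to a daily series.
    """
    values = np.asarray(values, dtype=float)
    moved = np.moveaxis(values, axis, 0)
    nt = moved.shape[0]
    flat = moved.reshape(nt, -1)
    out = flat.copy()
    idx = np.arange(nt)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        valid = np.isfinite(col)
        nv = int(valid.sum())
        if nv == 0:
            raise ValueError("gap_fill_linear: series is entirely missing")
        if nv < 2:
            out[:, j] = col[valid][0]
            continue
        out[:, j] = np.interp(idx, idx[valid], col[valid])
    return np.moveaxis(out.reshape(moved.shape), 0, axis)


def gap_fill_dataset(ds: xr.Dataset, variables: list[str] | None = None) -> xr.Dataset:
    """Gap-fill the listed time-dependent variables of a cube in place-copy."""
    out = ds.copy()
    for name in variables or [v for v in ds.data_vars if "time" in ds[v].dims]:
        da = out[name]
        taxis = da.dims.index("time")
        out[name] = (da.dims, gap_fill_linear(da.values, axis=taxis), da.attrs)
    return out


# ---------------------------------------------------------------------------
# Range QC
# ---------------------------------------------------------------------------

def qc_range(
    values: np.ndarray,
    bounds: tuple[float, float],
    name: str = "field",
) -> tuple[np.ndarray, QCReport]:
    """Mask values outside ``bounds`` (set to NaN) and report counts."""
    lo, hi = bounds
    if not (np.isfinite(lo) or lo == -np.inf) or hi < lo:
        raise ValueError(f"invalid bounds for {name}: {bounds}")
    values = np.asarray(values, dtype=float)
    bad = np.isfinite(values) & ((values < lo) | (values > hi))
    cleaned = np.where(bad, np.nan, values)
    report = QCReport(field=name, n_total=values.size, n_masked=int(bad.sum()))
    if report.n_masked:
        log.info("qc_range: %s — masked %d/%d values outside [%s, %s]",
                 name, report.n_masked, report.n_total, lo, hi)
    return cleaned, report


def qc_dataset(ds: xr.Dataset) -> tuple[xr.Dataset, list[QCReport]]:
    """Apply the standard physical-range QC to every known variable."""
    out = ds.copy()
    reports = []
    for name, bounds in PHYSICAL_BOUNDS.items():
        if name in out:
            cleaned, rep = qc_range(out[name].values, bounds, name)
            out[name] = (out[name].dims, cleaned, out[name].attrs)
            reports.append(rep)
    return out, reports


# ---------------------------------------------------------------------------
# NetCDF / raster / CSV round trips
# ---------------------------------------------------------------------------

def write_cube(ds: xr.Dataset, path: str | Path) -> None:
    """Write a forcing or ET cube as classic NetCDF (scipy backend)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    enc = {v: {"dtype": "float32"} for v in ds.data_vars}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_cube(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_raster(array: np.ndarray, path: str | Path, grid: GridSpec | None = None) -> None:
    """Write a 2-D (or band-stacked 3-D) float32 map as TIFF.

    Georeferencing (grid origin, cell size, CRS) is written to a JSON
    sidecar next to the TIFF.
    """
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32),
                     photometric="minisblack")
    if grid is not None:
        Path(str(path) + ".json").write_text(json.dumps(grid.to_dict(), indent=2))


def config_provenance(config: Mapping | RunConfig) -> str:
    """Serialize a run configuration for embedding in output metadata."""
    if isinstance(config, RunConfig):
        config = dataclasses.asdict(config)
    return json.dumps(config, sort_keys=True, default=str)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
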