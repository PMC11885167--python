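# ptjpl

Component-partitioned evapotranspiration modelling with scenario-based
attribution of climate vs. vegetation drivers, for basin-scale
ecohydrology studies.

Water-limited basins under rapid vegetation greening face a central
question: how much of the change in evapotranspiration (ET) is driven by
the climate, and how much by the vegetation itself? This package answers
it with a fully testable desk-scale pipeline: a Priestley-Taylor Jet
Propulsion Laboratory (PT-JPL) model that splits daily ET into canopy
transpiration, soil evaporation and interception evaporation; controlled
simulation experiments that freeze selected drivers at a baseline annual
cycle; difference regressions that turn those experiments into per-driver
sensitivities; and trend, turning-point and correlation analyses of the
results. A seeded synthetic-forcing generator emulating a temperate
monsoon basin (seasonal cycles, greening NDVI trend, 16-day composite
vegetation sampling, AR(1) weather noise) makes every stage reproducible
without external data.

## The model

Daily actual ET is the sum of three components, each a downscaled
Priestley-Taylor potential evaporation:

```
ET   = ET_c + ET_s + ET_i
ET_c = (1 − f_wet) f_g f_T f_M · α Δ/(Δ+γ) · R_nc / λ
ET_s = (f_wet + f_SM (1 − f_wet)) · α Δ/(Δ+γ) · (R_ns − G) / λ
ET_i = f_wet · α Δ/(Δ+γ) · R_nc / λ
```

with α = 1.26 the Priestley-Taylor coefficient, Δ the slope of the
saturation vapor pressure curve (Tetens form), γ ≈ 0.066 kPa/°C the
psychrometric constant, and λ = 2.45 MJ/kg converting energy to water
depth. Net radiation is partitioned between canopy and soil by the
Beer–Lambert law, `R_ns = Rn·exp(−k_Rn·LAI)` with k_Rn = 0.6, and LAI is
inverted from NDVI through `f_IPAR = m₂·NDVI + b₂` (m₂ = 1.0, b₂ = −0.05)
and `LAI = −ln(1 − f_IPAR)/k_PAR` (k_PAR = 0.5). The five eco-physiological
constraints are f_wet = (Rh/100)⁴, f_g = f_APAR/f_IPAR, f_T =
exp(−((Tm−T_opt)/T_opt)²), f_M = f_APAR/f_APAR,max and f_SM =
(Rh/100)^(VPD/β).

Attribution runs a normal simulation (`S_ALL`) against runs with climate
(`S_CLI0`) or vegetation (`S_NDVI0`) frozen at the first year's daily
cycle, then fits intercept-free least-squares regressions of the annual
ET differences on the driver differences:

```
ΔET(S_ALL − S_NDVI0) = β_NDVI ΔNDVI + ε
ΔET(S_ALL − S_CLI0)  = β_Tm ΔTm + β_Rh ΔRh + β_Rn ΔRn + ε
```

Trend turning points use a continuous broken-stick model
`y = β₀ + β₁t (+ β₂(t−a) for t > a)` fitted by exhaustive search over the
break year `a`; model validation uses R, RMSE, bias and Nash–Sutcliffe
efficiency, with a Bowen-ratio-preserving energy-balance-closure
correction available for flux-tower observations.

## Worked example

```python
import ptjpl

cfg = ptjpl.ForcingConfig(rows=10, cols=10, seed=42)   # greening basin
forcing = ptjpl.prepare_forcing(ptjpl.generate_grid_forcing(cfg))
et = ptjpl.compute_et(forcing)

annual = ptjpl.annual_aggregate(
    et[["ET", "ET_c", "ET_s", "ET_i"]], "sum"
).mean(["y", "x"]).to_dataframe()
print("mean annual ET  = %.1f mm/yr" % annual["ET"].mean())
for name in ("ET", "ET_c", "ET_s", "ET_i"):
    tr = ptjpl.ols_trend(annual[name])
    print(f"{name:5s} trend = {tr.slope:+.2f} mm/yr (p = {tr.p_value:.3f})")

fits = ptjpl.attribute_et(forcing)
print(fits["climate"].table.round(3))
```

prints

```
mean annual ET  = 630.4 mm/yr
ET    trend = +1.35 mm/yr (p = 0.000)
ET_c  trend = +3.40 mm/yr (p = 0.000)
ET_s  trend = -2.65 mm/yr (p = 0.000)
ET_i  trend = +0.60 mm/yr (p = 0.000)
      beta      se      t      p
Tm  25.048   4.221  5.934  0.000
Rh   2.407   3.810  0.632  0.536
Rn  85.436  10.281  8.310  0.000
```

Under greening-only forcing the canopy transpiration trend is positive,
soil evaporation declines (Beer–Lambert shading moves energy from the
soil to the canopy), and the two partially cancel, leaving a small
positive total-ET trend — the signature pattern this pipeline is built to
quantify. The sensitivity table reads, e.g., +25.0 mm of annual ET per °C
of air-temperature difference between the normal and climate-frozen runs.

The same stages are available from a shell:

```
ptjpl simulate-forcing --seed 42 --out forcing.nc
ptjpl run-et --forcing forcing.nc --out et.nc
ptjpl attribute --forcing forcing.nc --out attr/
ptjpl trends --forcing forcing.nc --out trends/
ptjpl validate --site-csv site.csv --out stats.json
```

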