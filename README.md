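# etcast

Forecasting crop evapotranspiration (ETc) 1–5 days ahead for irrigation
advisory services, by combining three cheap data streams:

* **ground weather sensors** — daily temperature, humidity, wind, shortwave
  radiation from automatic weather stations;
* **multispectral satellite imagery** — per-field broadband albedo and leaf
  area index (LAI), retrieved from red/NIR surface reflectance with the
  CLAIR model and held constant between passes;
* **air-temperature forecasts** — ensemble NWP output reduced to daily
  per-site values and corrected for their systematic bias.

The package targets the users of open-field irrigation scheduling in
Mediterranean climates: agronomists and service developers who need
accumulated crop water requirements a few days in advance without paying
for the full set of forecast weather variables.

## Method

The current ETc and the crop coefficient are computed analytically with the
**one-step Penman–Monteith** equation: the crop's own albedo enters the net
radiation and the LAI sets the canopy surface resistance

```
ETc = 86400/λ · [Δ(Rn − G) + ρ cp (es − ea)/ra] / [Δ + γ(1 + rs/ra)]
rs  = 200/LAI  (LAI ≤ 4),  50 s m⁻¹ otherwise
ra  = ln[(2−⅔hc)/0.123hc] · ln[(2−⅔hc)/0.0123hc] / (0.41² u₂)
```

with Kc = ETc-PM,obs / ET0-PM,obs, where ET0 is the FAO-56 grass reference.
Forecasts then need **only temperature**: a locally calibrated
Hargreaves–Samani estimate

```
ET0-HS = kHS · 0.0023 · (T + 17.8) · √(Tmax − Tmin) · 0.408 Ra
ETc-HS(t0 + Δt) = Kc(t0) · ET0-HS(t0 + Δt)
```

driven by bias-corrected ensemble temperature forecasts (median across
members per 3-hourly step, mean of the eight steps per day, minus the mean
forecast−observation difference of a reference period, per site and lead).
A comparison path evaluates the one-step Penman–Monteith directly on the
full forecast variable set. Verification reports BIAS and RMSE against the
one-step best estimate, per site, lead and 1/3/5-day accumulation horizon.

## Worked example

```
$ python examples/01_reference_and_crop_et.py
ET0 (grass reference)   :  5.65 mm/day
ETc (one-step, maize)   :  6.92 mm/day
crop coefficient Kc     :  1.23
```

A dense mid-season maize canopy (LAI 4.5, albedo 0.19) transpires ~23% more
than the reference grass under the same mid-July weather — the Kc the
one-step approach derives analytically instead of reading from tables.

```
$ python examples/04_forecast_and_verify.py
median skill across the 18 stations (ETc accumulated over horizon):
horizon  path   BIAS (mm)  RMSE (mm)
   1     HS       -0.05       0.74
   3     HS       -0.24       1.92
   5     HS       -0.58       3.19
   1     PM        0.05       0.65
   3     PM        0.20       1.47
   5     PM        0.27       2.49
```

On the fully synthetic 18-station experiment the temperature-only forecasts
reach a median RMSE of ~0.75 mm for the first day, growing with the
accumulation horizon as daily errors stack, and stay comparable to the
full-variable Penman–Monteith path.

The same pipeline is scriptable from the shell (`etcast simulate`,
`calibrate`, `retrieve-canopy`, `forecast`, `evaluate`); see
`etcast --help` and `etcast print-config`.

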