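# Methods

## Scope and model chain

`etcast` estimates and forecasts the evapotranspiration of a well-watered
open-field crop (ETc) at daily resolution. The chain is:

1. **Psychrometrics and radiation** (`etcast.meteo`) — FAO-56 daily
   conventions throughout: saturation vapour pressure as the mean of
   e°(Tmax) and e°(Tmin); actual vapour pressure from mean relative
   humidity; Δ at (Tmax+Tmin)/2; barometric pressure from elevation unless
   the station reports it; γ = 0.000665·P; air density from the ideal-gas
   law at the virtual temperature; extraterrestrial radiation Ra from solar
   geometry; net radiation as (1−α)·Rs minus the FAO-56 net longwave.
2. **Canopy retrieval** (`etcast.canopy`) — broadband albedo as an
   irradiance-weighted sum of band reflectances; LAI by inverting the CLAIR
   relation WDVI = WDVI∞·(1 − e^(−α*·LAI)) with WDVI = ρNIR − C·ρred.
   Retrievals are held constant until the next satellite pass (step
   function), as operational services do.
3. **ET estimators** (`etcast.et`) — the FAO-56 reference ET0; the one-step
   crop Penman–Monteith with canopy albedo and LAI-driven surface
   resistance (200/LAI up to LAI = 4, then 50 s m⁻¹, continuous at the
   break) and crop-height-driven aerodynamic resistance; and the
   Hargreaves–Samani temperature-only estimate with scaling factor kHS.
4. **Forecast preparation** (`etcast.nwp`) — triangle-based (barycentric)
   interpolation of the three nearest grid nodes to a station; ensemble
   median per 3-hourly step, then the mean of the eight steps per day;
   daily forecast extremes as the max/min of the eight stepwise medians;
   mean-bias correction of temperature per site and lead, fitted on a
   reference period.
5. **Calibration** (`etcast.calibration`) — kHS by least squares through
   the origin against the Penman–Monteith reference over past irrigation
   seasons (June 1–September 30); the closed form Σhp/Σh² is the exact
   argmin of the summed squared differences because the model is linear in
   kHS.
6. **Forecasting** (`etcast.forecast`) — Kc(t0) = ETc-PM,obs/ET0-PM,obs
   from the issue-day weather and the held canopy; the HS path multiplies
   Kc(t0) by the calibrated Hargreaves–Samani estimate driven by corrected
   forecast temperature; the comparison PM path evaluates the one-step
   equation on the full forecast variable set with the same held canopy.
   Daily values are accumulated to 1/3/5-day horizons.
7. **Verification** (`etcast.evaluation`) — BIAS = mean(f−o) and
   RMSE = √mean((f−o)²) against the one-step best estimate computed from
   observed weather; box-plot summaries across sites with linear-interpolated
   quartiles and Tukey fences at 1.5·IQR.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| reference albedo | 0.23 | – | FAO-56 grass reference |
| crop height h_c | 0.4 | m | common maize practice; ETc sensitivity over 0.1–0.6 m is negligible, configurable |
| CLAIR α* | 0.35 | – | field-verified extinction/scattering value for the target maize area |
| CLAIR WDVI∞ | required (0.50 in the synthetic sensor) | – | sensor/site specific asymptote; no universal default exists |
| soil-line slope C | 1.2 | – | NIR/red soil reflectance ratio; exposed per sensor |
| λ | 2.45 | MJ kg⁻¹ | fixed FAO-56 convention; no temperature dependence |
| G | 0 | MJ m⁻² day⁻¹ | daily-scale soil heat flux convention |
| calm-wind floor | 0.1 | m s⁻¹ | the aerodynamic resistance diverges at u₂ = 0 |
| Kc floor on ET0 | 0.1 | mm day⁻¹ | the ratio is numerically meaningless below it |
| bias-correction scope | temperature only | – | temperature is the one variable whose systematic error the mean-bias removal improves reliably everywhere |

## Numerical choices

* Shortwave radiation is stored in W m⁻² at every data interface (what
  stations report) and converted by ×0.0864 to MJ m⁻² day⁻¹ in exactly one
  constant, so unit errors cannot creep in between the numerator and
  denominator of Kc.
* The one-step equation evaluates the bracketed flux in W m⁻² (cp in
  J kg⁻¹ K⁻¹, Rn converted) and then converts to water depth via
  86400/(λ·10⁶). The check that grass parameters (albedo 0.23, h_c 0.12 m,
  r_s 70 s m⁻¹) reproduce the reference ET0 to well under 2% relative over
  10⁴ random weather draws pins this unit handling.
* Rs/Rso in the net-longwave term is clamped to [0.3, 1.0], and treated as
  1 when Ra = 0, so overcast and polar-night days stay physical. The
  sunset-hour-angle argument is clamped to [−1, 1], making polar night an
  exact zero rather than a NaN.
* Negative computed ET (rare longwave-dominated days) clamps to 0 with a
  warning. Negative WDVI (bare/wet soil) clamps LAI to 0; WDVI at or above
  the asymptote raises a saturation error rather than returning infinity.
* Quartiles use linear interpolation between order statistics — fixed
  purely for reproducibility of the box summaries.
* Collinear interpolation nodes fall back to inverse-distance weighting; a
  site outside its forecast triangle is projected onto the nearest edge.

## Synthetic data: what it emulates and what it does not

The generator (`etcast.synthetic`) reproduces the statistical structure the
methodology assumes, not the physics of an atmosphere:

* **Weather** — per-station seasonal harmonic plus AR(1) anomalies
  (persistence 0.7), diurnal range ~N(10, 2) °C, radiation as a clearness
  ratio times the elevation-dependent clear-sky cap (never above it).
  Default climatologies are an 18-station Mediterranean network spanning
  1–848 m elevation, 20–26 °C summer means and 1.1–4.4 m s⁻¹ winds.
* **Forecasts** — member value = truth + systematic bias + a shared daily
  error whose sd grows 20 %/lead-day + member dispersion, at 3-hourly steps
  whose diurnal shapes preserve the daily mean and extremes exactly.
  Temperature carries a −0.68 °C systematic bias by default; other
  variables are unbiased. A 16-member ensemble is the default.
* **Canopy** — logistic LAI rise normalized to hit its maximum (default 5)
  exactly at flowering, then slow linear senescence; albedo linear in LAI
  from 0.15 to 0.20; reflectances from the forward CLAIR map so retrieval
  round-trips to machine precision.

Because the synthetic "truth" ETc is produced by the same Penman–Monteith
physics the estimators use, passing tests demonstrate the internal
consistency, unit handling and error-propagation behaviour of the pipeline —
not the field accuracy of the equations against lysimeter or eddy-covariance
measurements, and not NWP error structures beyond an additive
bias+noise model (no error correlation between variables, no regime
dependence, no non-stationarity).

## Design choices where the design was open

* **Reduction order**: ensemble median per 3-hourly step first, then the
  daily mean of the eight medians; the alternative (daily mean per member,
  then median) is available behind `reduce_daily(member_first=True)`.
* **Forecast daily extremes**: max/min of the eight stepwise ensemble
  medians — a declared convention, since 3-hourly output has no canonical
  daily extremes.
* **Kc cadence**: Kc is recomputed every issue day from that day's weather
  while canopy parameters stay frozen between passes; freezing Kc entirely
  between images would couple the weather part of the ratio to stale days.
* **PM forecast path canopy**: held at the issue date t0, consistent with
  Kc frozen at t0. Under a zero-error forecast this makes the PM path's
  residual exactly the cost of holding the canopy, which the end-to-end
  test isolates.
* **Bias keying**: per (site, variable, lead); only temperature columns are
  corrected by default, and all three daily temperature statistics
  (mean/max/min) get their own fitted bias.
* **Experiment scale**: the end-to-end synthetic run uses 18 stations × one
  122-day evaluation season × 5 leads × 16 members, with four reference
  seasons (488 days) for calibration — a single-CPU scale chosen so the full
  replica runs in seconds while keeping every sample size at its operational
  value.

## Known limitations

* Daily time step only; no hourly Penman–Monteith, no dew-point humidity
  path, no precipitation handling or soil-water balance.
* Single-parameter Hargreaves–Samani calibration (the exponent 0.5 and the
  17.8 °C offset stay fixed).
* Canopy values are per-field scalars; raster ingestion beyond reducing a
  polygon to its mean reflectance is out of scope, as are atmospheric
  correction and cloud masking (assumed done upstream).
* Mean-bias correction only; no EMOS/Kalman-style post-processing of the
  ensemble.
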