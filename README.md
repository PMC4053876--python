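# paqikit

Satellite-driven assessment of particulate air pollution: estimate ground-level
PM10 and PM2.5 concentrations from aerosol and meteorological rasters with a
Levenberg–Marquardt back-propagation network, convert them to individual
air-quality indexes, combine those into a composite particulate air-quality
index (PAQI) with extreme-value weight handling, and summarize population
exposure per administrative zone.

The toolkit is aimed at air-quality and environmental-health researchers who
want the full chain — retrieval-style concentration estimation, indexing, and
exposure statistics — as reusable, testable components. A synthetic-domain
generator emulates the whole input stack (satellite aerosol optical thickness
and single-scattering albedo, reanalysis meteorology, gridded population,
province-like zones) on one co-registered grid, so everything runs and is
verified without external data; every stage equally accepts real rasters in
GeoTIFF or NetCDF.

## Methods at a glance

**Concentration estimation.** Candidate inputs (latitude, longitude, wind
speed WS, relative humidity RH, skin temperature SKT, boundary-layer height
HPBL, aerosol optical thickness AOT, single-scattering albedo SSA) are
screened by stepwise regression (partial-F entry/exit). A feed-forward
network with one tanh hidden layer (default 16 nodes) and a linear output is
trained by Levenberg–Marquardt damped Gauss–Newton on the sum of squared
errors, repeated over many random train/validation splits; the run with the
highest validation Pearson r is kept. Accuracy is reported as r and the mean
absolute percentage error APE = mean(|Y_est − Y_obs| / Y_obs).

**Indexing.** The individual index of each pollutant is the piecewise-linear
breakpoint interpolation of the Chinese AQI standard,

    IAQI = I_lo + (I_hi − I_lo) · (C − C_lo) / (C_hi − C_lo).

The composite index starts from index-proportional weights Q_i = I_i / Σ_j I_j.
With s = #{Q_i < 0.05} and t = #{Q_i > 0.5}, when both an extremely small and
an extremely large weight are present (s ≥ 1 and t ≥ 1, e.g. a dust storm
where the PM10 index dwarfs the PM2.5 index), the near-zero weights are
truncated to 0 and the rest renormalized, giving modified weights P_i; then
PAQI = Σ P_i · I_i.

**Exposure.** Per zone over valid cells: population-weighted concentration
PW-PM2.5 = Σ PM_i·P_i / Σ P_i (µg/m³) and the per-capita statistic
PC-PM2.5 = Σ PM_i·P_i / n with n the zone's cell count.

## Worked example

```python
import numpy as np
from paqikit import (SimConfig, simulate_fields, simulate_population, simulate_zones,
                     sample_stations, train_lm, predict_grid, iaqi, paqi, paqi_grid,
                     default_breakpoints, zonal_report, classify)

cfg = SimConfig(seed=1)                      # 40x40 grid, 300 stations, 5 zones
fields = simulate_fields(cfg)
stations = sample_stations(fields, cfg, pollutant="PM2.5")
model, report = train_lm(stations, hidden=16, n_runs=50, seed=1)
best = report.runs.iloc[report.best_run]
print(f"validation r = {best['r']:.3f}, APE = {best['ape']:.1f}%")

pm25 = predict_grid(model, fields)
tables = default_breakpoints()
i25 = pm25.with_values(iaqi(pm25.values, tables["PM2.5"]), name="IPM2.5")

stations10 = sample_stations(fields, cfg, pollutant="PM10")
model10, _ = train_lm(stations10, hidden=16, n_runs=50, seed=1)
pm10 = predict_grid(model10, fields)
i10 = pm10.with_values(iaqi(pm10.values, tables["PM10"]), name="IPM10")

composite = paqi_grid({"PM2.5": i25, "PM10": i10})
print(f"domain-mean PAQI = {composite.values.mean():.1f} "
      f"({classify(composite.values.mean())})")

bundle = paqi([480.0, 20.0])                 # dust-storm configuration
print(f"dust storm: Q = {bundle.raw.round(2)}, P = {bundle.modified}, "
      f"PAQI = {bundle.value:.0f}")

pop = simulate_population(cfg)
zones = simulate_zones(cfg)
rep = zonal_report(pm25, pop, zones)
print(rep.records[["zone_name", "pw_pm25", "pc_pm25", "rank_pw"]].round(1).to_string(index=False))
```

Output:

```
validation r = 0.975, APE = 4.3%
domain-mean PAQI = 137.4 (lightly polluted)
dust storm: Q = [0.96 0.04], P = [1. 0.], PAQI = 480
zone_name  pw_pm25  pc_pm25  rank_pw
  zone_01    124.9   3008.3        4
  zone_02    127.6  26195.8        2
  zone_03    103.7 930811.5        5
  zone_04    160.0 598507.2        1
  zone_05    127.0   3115.8        3
```

The network recovers the domain's known nonlinear PM2.5 surface from 300
noisy stations (held-out r = 0.975; 4.3% mean percentage error). The
dust-storm line shows the extreme-value rule in action: the 0.04 weight of
the low index is truncated, so the composite follows the dominant pollutant
exactly. In the zonal table, zone 04 has the highest population-weighted
exposure, while PC-PM2.5 — which scales with total population — ranks the
small, densely populated zone 03 first instead.

The same chain is available from the shell:

```
paqikit run-all --seed 1 --out runs/demo --runs 50
```

which writes rasters (GeoTIFF), trained models (JSON), training logs and the
exposure CSV, plus a manifest with the configuration, seeds and SHA-256 of
every artifact: repeating the command reproduces every file bit-identically.

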