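# awpm

A daily-timestep simulator for crop water use over shallow groundwater. It
couples:

- a **four-zone soil water balance** — Thornthwaite–Mather storage
  bookkeeping for percolation, the Gardner analytical steady-state limit
  for capillary rise from a dynamic water table, and specific-yield
  water-table dynamics (`awpm.soil`);
- an **EPIC-style crop model** — heat-unit phenology, logistic LAI
  build-up and power-law decline, radiation-use-efficiency biomass with
  water/temperature stress, root growth and harvest-index yield
  (`awpm.crop`);
- an **actual-evapotranspiration module** — FAO-56 Penman–Monteith
  reference ET, an LAI-driven crop coefficient, Beer's-law partition into
  soil evaporation and transpiration, and linear moisture reduction of
  each (`awpm.weather`, `awpm.et`);
- a **scenario engine** — the daily coupling loop, a season runner, a
  7 groundwater-depth × 9 deficit-irrigation-treatment grid, and water /
  irrigation-water productivity metrics (`awpm.simulator`);
- an **evaluation toolkit** — MRE/RMSE/NSE/R²/b fit statistics,
  one-at-a-time parameter sensitivity, and d-factor ensemble uncertainty
  (`awpm.evaluation`).

A synthetic weather generator emulating an arid continental monsoon
climate (rain concentrated in July–August, exact seasonal totals) makes
every part of the package runnable and testable without external data.

Units throughout: water fluxes in mm d⁻¹, depths below surface in cm
(positive downward), temperatures in °C.

## CLI

```sh
awpm config --show-defaults          # print the full default configuration
awpm run --config cfg.yaml --out d/  # one season: daily.csv + summary.csv
awpm grid --out grid.csv             # the 63-cell scenario table
awpm fixture --gwd 150 --seed 1 --out weather.csv
awpm eval --sim sim.csv --obs obs.csv
awpm sensitivity --parameter crop.lai_mx --index ET
```

The run configuration is a single YAML file with `weather`, `soil`,
`crop`, `et` and `scenario` blocks; any omitted key falls back to the
shipped defaults (loam soil, maize crop, Hetao-like climate preset). The
weather file format is comma-delimited with header
`date,tmax,tmin,sunshine,rh,wind,rain` (a `radiation` column may replace
`sunshine`).

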