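# n2oproj

Dynamic vs static emission-factor (EF) projection of fertilizer-induced
agricultural soil N₂O, exercised end-to-end on synthetic worlds.

The package builds a small synthetic planet — a cell grid with soil,
monthly climate, a skewed baseline fertilizer map and a known nonlinear
"true" EF response surface — then trains a machine-learning EF emulator on
it, projects 2010–2050 emissions under seven policy × climate scenarios
(INMS1–7, paired with SSP pathways) over a biased pseudo-GCM member
ensemble, and analyses reduction-goal timelines and hotspot-prioritized
nitrification-inhibitor (NI) mitigation. Because the truth surface is
closed-form, every stage of the pipeline is checkable against an
independent oracle.

## Modules

| Module | Role |
|---|---|
| `synthetic_world` | Grid/soil/climate/fertilizer generators, truth EF surface, training table |
| `climate_ensemble` | Delta bias correction, Thornthwaite-style aridity index, annual features |
| `scenario_fertilizer` | NUE trajectories per country/policy, fertilizer totals, pattern-preserving grid scaling |
| `ef_engine` | EF emulator (seeded tree ensemble), dynamic/static emission computation, truth validation |
| `projection_core` | Ensemble projection, median/p25–p75 bands, relative & cumulative changes, goal years, regional totals, CO₂e conversion, static-vs-dynamic gap |
| `hotspot_mitigation` | Hotspot ranking, top-fraction shares, NI adoption curves, minimal adoption area, expedited timelines |

## CLI

```bash
n2oproj synth --config config.yaml --out-dir out/world       # generate a world
n2oproj scenarios --out-dir out/scen                         # country trajectories (CSV)
n2oproj train --out out/emulator.joblib                      # fit + save the EF emulator
n2oproj project --out-dir out/proj --scenarios INMS1,INMS4   # ensemble summaries (CSV)
n2oproj hotspots --out-dir out/hot --scenario INMS3 --goal 0.25
```

`config.yaml` is optional (defaults: 2000 cells, 18 countries, 37 members,
years 1990–2050); write one with `WorldConfig(...).to_yaml(path)`. The
`seed` field drives all randomness.

## Notes

- Emissions are direct, fertilizer-induced N₂O-N only; unfertilized cells
  emit zero. Static method uses a fixed 1% EF; dynamic uses the emulator.
- GWP₁₀₀ defaults to 265 per unit N₂O mass (256 available via
  `ConversionConstants(gwp100=256)`).
- NetCDF output uses the scipy backend (classic NetCDF3), so no extra
  libraries are required.
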