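# greenkeeper

Decision support for nitrogen (N) fertilization of sand-based creeping-bentgrass
putting greens, plus a seeded "virtual putting green" simulator so the dosing
strategies can be run, compared, and validated end to end without field data.

Four dosing strategies are implemented:

- **Growth-potential (GP) dosing** — a Gaussian temperature index (1.0 at the
  20 °C cool-season optimum, spread 5.5 °C) scales a calibrated maximum daily
  N use rate over each 14-day interval (`greenkeeper.gp_model`).
- **Experience schedule** — a fixed 10 kg ha⁻¹ every other week across a
  ~30-week season (`greenkeeper.schedule_strategies`).
- **NDRE threshold rule** — withhold fertilizer when the 14-day mean NDRE
  exceeds the 0.28 virtual-reference threshold, otherwise apply 10 kg ha⁻¹
  (`greenkeeper.schedule_strategies`).
- **Growth-prediction (ML-RF) dosing** — a seeded random-forest regressor
  trained on prior-season clipping data predicts 2-week cumulative clipping
  yield; doses replace the predicted N removal inside a 17.5–22.5 g m⁻²
  target band (`greenkeeper.mlrf_growth`).

Supporting modules: the simulator (`greenkeeper.synthetic_green`), summary
metrics — N budgets, NUE, percent reductions, clipping→quality mapping,
prediction-ratio statistics, NDRE–clipping correlation
(`greenkeeper.evaluation`), policy adapters (`greenkeeper.policies`), and a
trial orchestrator (`greenkeeper.cli_pipeline`).

## CLI

```sh
# synthesize a season of daily weather
greenkeeper simulate-weather --seed 7 --days 210 --out weather.csv

# single-rule recommendations
greenkeeper gp-dose --weather weather.csv --interval 14 --max-growth 3.2 --tissue-n 0.039
greenkeeper experience-dose --date 2020-05-15 --season-start 2020-05-01
greenkeeper ndre-dose --history ndre.csv --date 2020-07-01 --threshold 0.28

# growth-prediction workflow
greenkeeper mlrf-train --obs obs.csv --weather weather.csv --fert fert.csv \
    --root-zone A --out model.joblib
greenkeeper mlrf-recommend --model model.joblib --features next14.csv

# plot evaluation (N budget, NUE, NDRE-clipping correlation)
greenkeeper evaluate --obs obs.csv --fert fert.csv --control-obs control.csv

# full virtual trial from a YAML config
greenkeeper run --config trial.yaml --outdir out/
```

A minimal trial config:

```yaml
master_seed: 1
years: 2            # first year trains the growth model, later years decide
replicates: 4
strategies: [gp, experience, mlrf, ndre]
climate: {season_length_days: 210, mean_peak_temp: 22.5}
zones:
  - {zone_id: A, som_level: 0.7}
  - {zone_id: B, som_level: 1.2}
```

`run` writes `report.csv` (one row per plot × strategy: cumulative N,
clipping, uptake, NUE), `report.json` (full summary plus every seed needed to
reproduce the trial), `fertilization_log.csv`, and `observations.csv`.

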