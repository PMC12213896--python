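# thermorad

Virtual-trial simulation of tumour responses to radiotherapy (RT),
high-temperature hyperthermia (HT) and their combination.

The package implements a dimensionless ODE model of tumour, vasculature and
oxygen dynamics with piecewise-constant treatment forcing (fractionated RT
dose rate, weekly HT damage rate, heat-induced repair-protein inactivation),
and the analysis pipeline built on top of it:

- **`model_core`** — parameters, state, forcing functions, repair-inhibition
  kinetics and the seven-component right-hand side;
- **`equilibria`** — untreated fixed points, nutrient-limited (NL) /
  space-limited (SL) / bistable (BS) regime classification, and the sampling
  thresholds q̄1, q̄3;
- **`cohorts`** — seeded virtual tumour populations drawn from
  regime-specific uniform boxes, with baseline steady states;
- **`schedules`** — RT/HT/combined treatment plans on a minute clock under
  an 80 Gy radiation cap and a 0.08 total thermal-dose cap;
- **`simulate`** — discontinuity-aware integration (restart at every window
  edge) with dense last-week output;
- **`response_metrics`** — percent-change metrics, five-class response
  stratification, deleterious flag;
- **`comparison`** — the three comparison rules, per-tumour best-treatment
  labels and the two-step regimen ranking;
- **`workbench`** — configuration, orchestration, CLI, manifests and
  optional figures.

## CLI

```sh
# sampling thresholds for a vascular volume
thermorad thresholds --v0 0.005 --q1 2.14

# sample a seeded cohort
thermorad cohort --regime BS -n 250 --seed 7 --out bs_cohort.csv

# one tumour, one schedule -> trajectory CSV
thermorad simulate --q1 0.151 --q3 0.210 --v0 0.005 \
    --modality RT_HT -d 2 --n-frac 5 --beta 0.005 --out traj.csv

# full study (cohorts, schedule grid, metrics, rules, ranking, manifest)
thermorad study --config config.yaml --outdir out/ --plots
```

A study config is a flat YAML mapping, e.g.

```yaml
cohorts:
  - {regime: NL, N: 250, seed: 1}
  - {regime: SL, N: 250, seed: 2}
  - {regime: BS, N: 250, seed: 3}
rt_grid: [[2.0, 5], [5.0, 1]]   # [dose Gy, fractions/week]
beta_grid: [0.001, 0.005, 0.01]
rtol: 1.0e-8
atol: 1.0e-10
rule2_mode: better
outdir: out
```

`sweep` and `compare` run the middle stages of the pipeline on existing CSV
files; see `thermorad --help`.

## Outputs

All outputs are plain text: per-cohort CSVs (`id, regime, q1, q3, V0,
T_star, c_star`), a responses CSV (one row per tumour × schedule pair ×
treatment with the four Δ metrics, combined score, response class and
deleterious flag), a comparison CSV (rule outcomes and winners per matched
pair), a ranked-outcome JSON and a manifest JSON recording seeds,
thresholds, tolerances and flag values.

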