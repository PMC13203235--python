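# troughvar

Patient-level analysis of trough-concentration variability for two-cohort
(pre/post protocol) therapeutic drug monitoring audits.

The package computes, per patient, the coefficient of variation (CV%), the
swing index ((Cmax − Cmin)/Cmean), the mean absolute successive difference
(MSSD), the trough range, zone-change counts, and a binary stability flag
(CV% < 20%). Each trough is classified into three zones (subtherapeutic
< 15 mg/L, target 15–20 mg/L, supratherapeutic > 20 mg/L; boundaries belong
to the target zone) and all within-patient consecutive zone pairs are pooled
into first-order Markov transition matrices per cohort. A nonparametric
comparison layer (Mann–Whitney U with rank-biserial effect size, Fisher's
exact test, Spearman correlations) contrasts the two cohorts, and a seeded
synthetic cohort generator makes the whole pipeline testable without any
clinical data.

## Modules

| Module | Purpose |
|---|---|
| `troughvar.data` | Tidy CSV/TSV I/O, validation, ordering by `seq_index`, minimum-measurement inclusion filter |
| `troughvar.metrics` | Per-patient variability metrics and cohort summaries (median/IQR) |
| `troughvar.zones` | Zone classification, zone-change counting, pooled 3×3 transition matrices, zone distributions |
| `troughvar.stats` | Mann–Whitney U (exact/asymptotic), rank-biserial (Cliff's delta), two-sided Fisher exact (point-probability), Spearman rho, comparison-table builder |
| `troughvar.simulate` | Seeded synthetic cohort generator (lognormal AR(1) and zone-chain modes, paper-shaped presets) |
| `troughvar.pipeline` / `troughvar.cli` | End-to-end runner, JSON summary, CSV/Markdown reports, CLI |

## Input format

Trough table (CSV or TSV, autodetected):

```
patient_id,cohort,seq_index,trough_mg_per_l
p001,pre,1,12.4
p001,pre,2,17.9
...
```

At most two cohort labels are allowed. Optional covariates table:
`patient_id, age, sex, egfr, weight_kg, therapy_days, n_dose_adjustments,
loading_dose_mg_per_kg, loading_dose_given`.

## CLI

```bash
# full pipeline on your own data
troughvar all --input troughs.csv --covariates cov.csv \
    --min-measurements 3 --target-low 15 --target-high 20 \
    --stable-cv 20 --seed 42 --out results/

# synthetic demonstration cohorts (51/309 and 17/94 patients/measurements)
troughvar simulate --preset primary --seed 42 --out sim/
troughvar all --preset primary --seed 42 --sensitivity --out results/

# individual stages
troughvar metrics --input troughs.csv --out results/
troughvar zones   --input troughs.csv --out results/
troughvar compare --input troughs.csv --out results/
troughvar report  --summary results/summary.json
```

`troughvar all` writes `summary.json` (full precision, deterministic for a
given input and seed), `metrics.csv`, `comparison.csv`/`.md`,
`zone_distribution.csv`, `transition_<cohort>.json`/`.csv`, and `run.log`.
`--sensitivity` reruns the analysis with a minimum of two measurements;
`--stratify-loading-dose` compares variability between loading-dose strata
within each cohort.

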