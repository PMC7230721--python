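# calorflex

Analysis pipeline for basal metabolism and substrate oxidation from
indirect-calorimetry recordings, with insulin-sensitivity indices,
metabolic-phenotype classification, and covariate-adjusted association
models — plus a seeded synthetic-data generator so the entire chain is
testable offline.

## Pipeline stages

1. **gas_exchange_io** — read/validate breath-by-breath trace CSVs
   (`t_s, vo2_ml_min, vco2_ml_min, ve_l_min`; other cart exports via a
   column-mapping dialect) and participant tables; average traces into
   fixed epochs (default 30 s, half-open tiling).
2. **steady_state** — discard the first 5 min, scan epoch-aligned 5-min
   windows, screen each on CV < 10% in VO2, VCO2, minute ventilation and
   RER, and select the most stable window (minimum mean of the four CVs,
   ties to the earliest start). Windows with mean RER outside [0.7, 1.0]
   keep their energy-expenditure output but are excluded from substrate
   oxidation.
3. **stoichiometry** — abbreviated Weir equation for basal metabolic
   rate (kcal/day) and Frayn equations for fat/carbohydrate oxidation
   (g/min), also expressed as % of BMR via configurable energy
   equivalents.
4. **clinical_indices** — BMI, lean/fat mass index, mean blood pressure
   (arithmetic mean of SBP and DBP), HOMA-IR, QUICKI, lipid ratios, and
   the four-way phenotype (MHNW/MUNW/MHOO/MUOO).
5. **association** — Shapiro–Wilk normality screen with automatic
   natural-log transform, sex t-tests, Models 0–3 regressions
   (unadjusted / sex / age / lean mass; standardized β, partial F,
   adjusted R²), and phenotype ANOVA/ANCOVA.
6. **synthetic_data** — seeded cohort and trace simulators with planted
   BMR, RER and RER↔ln-insulin effects for power and recovery checks.
7. **pipeline / cli** — one configured, logged, reproducible run.

## CLI

```bash
# generate a synthetic cohort with traces and hidden truth
calorflex simulate --n 57 --seed 1 --out sim/

# validate inputs / inspect steady-state selection
calorflex ingest --traces sim/traces --participants sim/participants.csv
calorflex steadystate --traces sim/traces --participants sim/participants.csv

# full run: metabolic results, indices, exclusion log, report tables, manifest
calorflex run --traces sim/traces --participants sim/participants.csv --out out/

# or driven by a YAML config mirroring RunConfig
calorflex analyze --config config.yaml
```

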