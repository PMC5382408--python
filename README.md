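# dismodkit

Incidence–prevalence–mortality (illness-death) modelling of aggregated
GP-registry morbidity counts.

Chronic-disease morbidity estimates from general-practice registration
networks vary widely, partly because registries differ in how they separate
new (incident) from existing (prevalent) cases — especially registries that
code *episodes of care* (a case is visible only when the patient contacts
the GP) rather than *episodes of disease*. This package provides the full
analysis pipeline for diagnosing and correcting that problem:

1. **`registry_io`** — read/validate/write aggregated registry tables
   (per network × disease × sex × 5-year age band: person-years, registered
   patients, prevalent/incident counts, deaths and institutionalizations
   among the diseased) and standard-population weights.
2. **`rates`** — observed incidence density (new cases per disease-free
   person-year) and point prevalence for both registry constructions,
   direct age–sex standardization, cross-network simple means and spread
   ratios, and a period life-table check on registry mortality.
3. **`ipm`** — discrete-time illness-death projection of a birth cohort
   under stationary rates, and observed-vs-projected prevalence consistency
   reports.
4. **`dismod_fit`** — joint maximum-likelihood estimation of an age-specific
   incidence curve (cubic polynomial on the log scale) together with a
   misclassification fraction κ (share of truly prevalent cases recorded as
   incident), holding mortality/institutionalization schedules fixed.
   Poisson likelihood for incident counts, binomial for prevalent counts;
   boundary handling for κ̂ = 0; parametric-bootstrap (multivariate-normal
   parameter draws) percentile CIs for standardized rates.
5. **`pooling`** — DerSimonian–Laird random-effects pooling of
   network-specific standardized rates on the log scale.
6. **`synthetic_data`** — a patient-level registry simulator (true
   illness-death process + Bernoulli care-seeking contacts + episode-of-care
   or episode-of-disease extraction with a lookback window) so the entire
   pipeline is testable without any confidential data.
7. **`cli`** — subcommands `simulate`, `rates`, `project`, `fit`, `pool`
   and an orchestrated `run`.

## CLI

```bash
# synthetic registry for one network
dismodkit simulate --preset knee_oa_like --population 100000 --seed 1 --out reg.csv

# observed standardized rates
dismodkit rates --registry reg.csv --stdpop stdpop.csv --out rates.csv

# observed vs projected prevalence (consistency check)
dismodkit project --schedules schedules.csv --observed reg.csv --out consistency.csv

# joint ML fit with bootstrap CIs
dismodkit fit --registry reg.csv --fixed-schedules schedules.csv \
    --stdpop stdpop.csv --seed 20100101 --out-json fit.json --out-csv fit.csv

# random-effects pooling across networks
dismodkit pool --estimates fit.csv --out pooled.csv

# whole pipeline on a five-network synthetic bundle
dismodkit run --preset diabetes_like --seed 7 --out-dir out/ --scale 0.1
```

`run` also accepts a plain `key = value` config file via `--config`
(keys: `out_dir`, `seed`, `preset`, `scale`, `draws`, `degree`, `stages`).

## File formats

Registry CSV columns: `network, disease, sex, age_lo, age_hi, person_years,
n_registered, prev_count, inc_count, deaths_with_disease, inst_with_disease,
seen_in_window` (UTF-8, header mandatory, empty cell = missing; ages are
half-open integer bands partitioning [0, 100); sex is `f`/`m`). Missing
`n_registered` is imputed as `round(person_years)` (stable-population
assumption). Standard-population CSV: `sex, age_lo, age_hi, weight`
(weights are renormalized to sum to 1).

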