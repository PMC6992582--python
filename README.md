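# euplokit

Toolkit for per-oocyte euploidy-probability prediction in IVF/ICSI with
PGT-A, built around four pieces:

- **calculator** — a contrast-coded logistic model giving the probability
  `p` that a mature (MII) oocyte becomes a euploid blastocyst from female
  age, sperm source, and treatment center, plus the minimum-oocyte count
  `MIImin = min{N : 1 - (1-p)^N >= pi}` for a chosen success probability
  `pi`. A validated multicenter coefficient set ships as the default;
  any coefficient set can be supplied as JSON.
- **cohort** — a synthetic CRF-style cohort simulator (truncated-normal
  ages, negative-binomial MII counts, binomial thinning through
  fertilization/blastulation so that euploid counts are marginally
  `Binomial(N, p)` under a ground-truth coefficient set).
- **fitting** — count-distribution identification (negative binomial vs
  Poisson by AICc), adaptive-Lasso covariate selection on the euploid-count
  response with an `log(N)` exposure offset, and the final aggregated
  binomial logistic fit that emits a pluggable coefficient set.
- **validation** — 75/25 holdout split, oocyte-level ROC/AUC
  (tie-corrected Mann-Whitney), Nagelkerke generalized R², model-vs-model
  comparison, predictive-value (PPV) contingency tables, Tukey-Kramer HSD,
  and an end-to-end pipeline producing a JSON report.

## CLI

```bash
# predict p and MIImin for one patient (center-free mode)
euplokit predict --age 35 --sperm ejaculate --center none --pi 0.7 --pi 0.8 --pi 0.9

# simulate a synthetic cohort (CRF CSV, seed-reproducible)
euplokit simulate --n 1464 --seed 7 --out cohort.csv

# refit the model on a CRF cohort
euplokit fit --crf cohort.csv --stage final --out coefs.json --report fit.json

# run the full validation pipeline (holdout AUC/R2, MIImin, PPV tables)
euplokit validate --crf cohort.csv --coefs coefs.json --pi 0.7 --pi 0.8 --pi 0.9 \
    --seed 11 --out report.json --roc-csv roc.csv

# summarize a report
euplokit report --in report.json
```

The CRF CSV schema (v1) has required columns
`patient_id, female_age, sperm_source, center, n_mii, n_2pn, n_blast, n_euploid`
with `n_euploid <= n_blast <= n_2pn <= n_mii`; extra columns are tolerated.
Lines starting with `#` carry provenance (seed, config digest) and are
ignored on read.

## Library use

```python
import euplokit as ek

coefs = ek.default_coefficients()
profile = ek.PatientProfile(35.0, ek.SpermSource.EJACULATE, ek.Center.UNSPECIFIED)
est = ek.predict(profile, pi=0.8, coefs=coefs)
print(est.p, est.mii_min, est.risk)

records = ek.generate_cohort(ek.CohortSpec(n_patients=1464, seed=7))
report = ek.run_validation_pipeline(records, ek.PipelineConfig(seed=11, reference=coefs))
print(report.metrics)
```
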