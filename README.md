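# curemix

Semiparametric **mixture cure** analysis of recurrence-free survival,
built for oncology cohorts in which a substantial fraction of patients
is cured by treatment and will never experience the event — the setting
of definitive (chemo)radiotherapy for cervical carcinoma, where only a
minority relapse with distant metastasis and an ordinary Cox model
(which assumes everyone eventually fails) misreads the plateau of the
survival curve.

The population survival is modelled as

    S(t | x, z) = 1 − π(z) + π(z) · Su(t | x)

with a logistic **incidence** model π(z) = expit(bᵀz) for the
probability of being uncured (susceptible), and a Cox
proportional-hazards **latency** model Su(t | x) = S0(t)^exp(βᵀx) for
time to recurrence among the uncured, estimated by EM with a
nonparametric Breslow baseline under the zero-tail constraint.
Incidence effects are reported as odds ratios of being uncured, latency
effects as hazard ratios; inference is by case-resampling bootstrap.

The package provides, as library modules with a thin `curemix` CLI:

* `survcore` — weighted Kaplan-Meier with Greenwood variance, log-rank
  test, weighted Breslow Cox fit (the EM's latency engine);
* `curemodel` — the EM estimator, bootstrap inference, cure-probability
  and median-uncured-time summaries, individualized marginal curves;
* `curetest` — a nonparametric one-sided test of H0: cure ≤ c0 at a
  follow-up horizon (KM-at-horizon estimator, cloglog scale), with a
  horizon × cure-level profile;
* `matching` — logistic propensity scores, greedy 1:1 nearest-neighbor
  matching without replacement, balance diagnostics, and the matched
  age-stratified subgroup analysis;
* `datagen` — synthetic cohorts with known mixture-cure truth, and
  cohorts matching printed marginal tables exactly;
* `pipeline` — schema-validated cohort I/O, variable encoding,
  descriptive tables with group tests, and the orchestrated end-to-end
  analysis.

## Worked example

Simulate a study-structured cohort (n = 446, true cure fraction 79.2%,
true median uncured recurrence time 1.60 y), then fit and test:

```python
import numpy as np
from curemix import (datagen, pipeline, CureDesign, em_fit,
                     predict_cure_probability, SurvivalSample,
                     km_estimate, survival_at, cure_probability_test)

cohort = datagen.simulate_cohort(datagen.study_cohort_spec(n=446, seed=11))
enc = pipeline.encode_analysis_variables(cohort.table)
df = enc.frame

sample = SurvivalSample(df.time_years.to_numpy(), df.event_metastasis.to_numpy())
km = km_estimate(sample)
print([round(100 * survival_at(km, y), 1) for y in (1, 3, 5)])
# [91.9, 84.7, 82.5]   <- 1/3/5-year recurrence-free rates (%)

for c0 in (0.7, 0.8):
    r = cure_probability_test(sample, tau=5.0, c0=c0)
    print(c0, round(r.p, 4))
# 0.7 0.0              <- 5-year cure probability exceeds 0.7 ...
# 0.8 0.1073           <- ... but 0.8 cannot be rejected

design = CureDesign.build(df, pipeline.DEFAULT_INCIDENCE,
                          pipeline.DEFAULT_LATENCY)
fit = em_fit(design)
print(round(100 * float(np.mean(predict_cure_probability(fit))), 1))
# 82.2                 <- estimated mean cure probability (%)
```

The cure-test p-values read as one-sided evidence that the cure
probability at the 5-year horizon exceeds the stated level; the fitted
cure probability averages 1 − π(z) over the cohort and lands near the
generating 79.2%.

The same analysis end-to-end, writing `table1.csv`, `table2.json`
(incidence OR / latency HR blocks with bootstrap SDs and p-values),
`table3.csv` (stratified cure probabilities and median uncured times),
`table4.json` (matched subgroup fits), KM curve exports, and the
cure-test profile:

```bash
curemix report --seed 11 --out results/run1
```

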