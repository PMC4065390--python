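# birthcheck

Detection of systemic birthdate contamination in person-level databases.

Health and administrative databases accumulate wrong birthdates through a
handful of systematic mechanisms — software "zero dates" (1899-12-30,
1970-01-01) substituted for missing values, day/month format confusion,
self-reported rounding to January 1st, age/year confusion, and systems that
copy event dates into the birthdate field. All of them concentrate many
records on a few calendar dates. `birthcheck` finds those dates from the
daily birthdate histogram alone, for data-quality teams who cannot manually
audit registers with tens of thousands of records.

## Method

The daily count N(d) of individuals born on day d is modelled as a
non-homogeneous Poisson process, N(d) ~ Poisson(λ(d)), with a smooth
log intensity

    log λ(d) = β₀ + s₁(d) + I(d ∈ weekend/holiday) · s₂(d)

where s₁ captures the register's demographic age profile plus annual
seasonality and s₂ the slowly drifting weekend birth reduction. Both
smooths are penalized regression splines (cubic P-splines by default,
rank min(2·years, 200) and 10), fitted by penalized IRLS with smoothing
parameters chosen by GCV. A day is flagged when its observed count is
improbable under the fitted pointwise Poisson law,

    P(K ≥ N(d) | λ̂(d)) < c        (default c = 10⁻⁴),

computed through the regularized incomplete gamma function. Because the
criterion is pointwise, sparse range ends are safe: a lone individual at
λ̂ = 0.05 has tail probability ≈ 0.049 and is never flagged. Optionally the
model is refitted with flagged days removed to counter masking by extreme
spikes. Seasonal-ARIMA residual thresholding (ARIMA(0,1,5)×(0,0,2)₇, global
99.99th-percentile cut) and sliding-window median/MAD smoothing are
included as comparison detectors, and a seeded synthetic-register generator
provides labelled ground truth.

## Worked example

```python
import numpy as np
from birthcheck import synthetic as syn
from birthcheck.detect import DetectionConfig, detect
from birthcheck.evaluation import confusion, metrics

ds = syn.generate(syn.standard_register_intensity(),
                  syn.standard_contamination(), seed=1)
report = detect(ds.series, det_cfg=DetectionConfig(c=1e-4))
print(report.results.summary())
print(report.table[report.table.flagged].head(4)[
    ["date", "count", "expected", "tail_prob", "rank"]])
print(metrics(confusion(report.flags, ds.truth)).as_dict())
```

```
Poisson birthdate GAM
==============================================
n days:            44925
basis:             cubic_penalized
rank s1 / s2:      200 / 10
smoothing params:  1e+04, 1e+08
edf (terms):       1.00, 23.23, 2.00
edf total:         26.23
GCV score:         0.918928
deviance:          41211.7
sum(lambda_hat):   39970.4937
sum(counts):       40670
converged:         True (1 iterations)
            date  count  expected     tail_prob  rank
3650  1899-12-30     45  0.177502  1.150521e-90   2.0
3652  1900-01-01     35  0.155073  3.882439e-69   4.0
7669  1911-01-01     30  0.703615  5.020901e-38  19.0
17205 1937-02-09      7  0.983518  7.515981e-05  24.0
{'TP': 24, 'FP': 2, 'FN': 1, 'TN': 44898, 'sensitivity': 0.96,
 'specificity': 1.0, 'ppv': 0.9231, 'fnr': 0.04, 'auc': None}
```

The register covers 44,925 days (1890–2012) with about 40,000 individuals.
The summary shown is the model after one masking-mitigation refit, in which
the flagged days carry zero weight — which is why `sum(lambda_hat)` matches
the observed total over the *retained* days only, and why the selected
flexibility (edf 26) is far below the initial fit's (the spikes no longer
force wiggle room). The detector recovers 24 of the 25 injected
contamination dates — the 1899-12-30 and 1900-01-01 zero dates, a 1911/2011
year confusion, New-Year and decade rounding, a duplicated identity and a
cluster of dispensing-date copies — with two false positives (the
1937-02-09 row, a day whose count of 7 is merely unlucky under λ̂ ≈ 0.98).
`expected` is the fitted intensity λ̂(d) and `tail_prob` the pointwise
Poisson tail probability that drives the flagging; ranking falls back to
the log count/intensity ratio where the tail underflows.

The same pipeline is available from the shell:

```bash
birthcheck simulate --scenario standard --seed 1 --out sim/
birthcheck detect --input sim/counts.csv --input-kind counts --out run/
birthcheck compare --counts sim/counts.csv --labels sim/labels.csv --out cmp/
```

## Layout

| module | contents |
| --- | --- |
| `birthcheck.calendar_counts` | strict date-dialect parsing, aggregation to dense daily series, weekend/holiday indicator |
| `birthcheck.splines` | P-spline and reduced-rank thin-plate bases with penalties |
| `birthcheck.gam` | `BirthdateGAM` model, P-IRLS, GCV selection, `GAMResults` |
| `birthcheck.detect` | Poisson tail/quantile primitives, flagging, iterative refit |
| `birthcheck.baselines` | seasonal-ARIMA and median/MAD comparison detectors |
| `birthcheck.synthetic` | labelled synthetic register generator and scenarios |
| `birthcheck.evaluation` | confusion counts, sensitivity/specificity/PPV/FNR, ROC/AUC |
| `birthcheck.cli` | `birthcheck detect / simulate / evaluate / compare` |

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
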