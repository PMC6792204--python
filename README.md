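# utilmap — FACT-B → EQ-5D-5L health-utility mapping

Cost–utility analysis needs preference-based utilities (for QALYs), but
breast-cancer studies usually collect the disease-specific FACT-B
questionnaire instead of the EQ-5D. `utilmap` implements a published
mapping (crosswalk) from FACT-B scores to EQ-5D-5L utility values developed
on Chinese breast-cancer patients, and re-implements the full
model-development pipeline so the mapping can be re-derived and validated
on any cohort — including fully synthetic ones that ship with the package.

It is aimed at health-economics and outcomes researchers who have FACT-B
data (37 items, five subscales: PWB, SWB, EWB, FWB, BCS; total 0–148) and
need EQ-5D-5L utilities they did not collect.

## What it computes

**Published coefficient sets.** Nine models shipped in a versioned
registry: `OLS1`–`OLS5` (a specification ladder from total score to domain
scores with squared and interaction terms), `TOBIT4`/`TOBIT5`
(upper-censored regression), `TPM4`/`TPM5` (two-part). The headline model
is the full OLS polynomial

u = −0.9110 + 0.05918·PWB + 0.01932·EWB + 0.02086·FWB + 0.03505·BCS
− 0.00030·PWB² − 0.00029·EWB² + 0.00006·FWB² + 0.00011·BCS²
+ 0.00006·PWB·EWB − 0.00019·PWB·FWB − 0.00111·PWB·BCS
− 0.00019·EWB·FWB − 0.00019·EWB·BCS − 0.00036·FWB·BCS,

optionally followed by linear equating
Y = μ_Y + (σ_Y/σ_X)(X − μ_X) to counter regression to the mean.
Tobit models predict via the latent index x'β (the residual scale was not
published; the censored expectation E[min(Y*,1)] is available when σ is
supplied). Two-part models combine a logistic ceiling probability with a
conditional linear mean: p̂·1 + (1−p̂)·ŷ₂.

**Model development.** OLS, upper-censored Tobit by maximum likelihood,
logistic regression, and two-part assembly; the five-stage specification
ladder with two-tailed p < 0.10 term retention; goodness of fit (r² as the
squared observed–predicted Pearson correlation, adjusted
r² = 1 − ((n−1)/(n−p−1))(1−r²), RMSE, MAD, MAE, AIC, BIC); seeded 5-fold
cross-validation scored by MAE.

**Instruments.** FACT-B scoring from item responses (reverse-scoring of
negatively worded items, ≥50% proration for missing items) and EQ-5D-5L
tariff application from user-supplied value-set CSVs (full 3125-state
tables or additive decrements). Tariff values are data, not code.

**Synthetic cohorts.** A generator that emulates the development study's
marginals (n = 446, utility mean ≈ 0.857 with ~25% at the ceiling of 1,
FACT-B total mean ≈ 104, Spearman ≈ 0.64) so the whole pipeline is testable
without patient data.

## Worked example

```python
import pandas as pd
from utilmap import published_coefficients, predict_linear, equate, EquatingParams

scores = pd.DataFrame({"pwb": [26, 18, 8], "swb": [24, 20, 10],
                       "ewb": [22, 14, 6], "fwb": [25, 16, 7],
                       "bcs": [36, 24, 12]})
ols5 = published_coefficients("OLS5")
pred = predict_linear(ols5, scores)
params = EquatingParams(mu_x=0.857, sigma_x=0.161, mu_y=0.857, sigma_y=0.193)
print(pred, equate(pred, params))
```

prints (mild / moderate / severe impairment):

```
OLS5:          0.966  0.761  0.068
OLS5 equated:  0.987  0.741 -0.089
```

A utility of 0.966 means near-full health; equating stretches the
predictions to the observed spread, so poor health maps lower (−0.089,
a state valued worse than dead) and good health higher. Refitting the
ladder on a synthetic cohort (`examples/04_refit_pipeline.py`) prints:

```
model  terms    r2  adj_r2  rmse   mae     aic    bic
 OLS1      1 0.535   0.534 0.105 0.081  -738.9 -726.6
 OLS2      5 0.632   0.628 0.093 0.072  -835.1 -806.4
 OLS3      4 0.632   0.629 0.093 0.072  -837.0 -812.4
 OLS4      8 0.730   0.725 0.080 0.060  -967.0 -926.0
 OLS5     11 0.758   0.752 0.076 0.058 -1009.2 -955.9
```

— the squared/interaction stages buy most of the fit, and SWB drops out of
the ladder at stage 3, both as in the development study. The
`examples/` directory holds one short script per capability (scoring,
value sets, published mapping, refitting, cross-validation).

A thin CLI wraps the same functions:

```sh
utilmap simulate --n 446 --seed 1 --out cohort.csv
utilmap fit --family ols --stage 5 --in cohort.csv --out fit.json
utilmap evaluate --fit fit.json --in cohort.csv --cv 5 --seed 1 --out report.json
utilmap map --model OLS5 --in scores.csv --out utilities.csv
```

## Limitations

The Chinese EQ-5D-5L tariff values are not redistributed here; supply them
as a value-set CSV to convert observed EQ-5D profiles. Published Tobit sets
cannot compute the censored expectation (σ unpublished). The mapping was
developed on breast-cancer patients in one country; transporting it to
other populations is the user's responsibility. See `docs/methods.md` for
the modelling assumptions and numerical choices.
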