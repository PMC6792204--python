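# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the published
description left the choice open.

## The mapping problem

A mapping (crosswalk) predicts a preference-based utility — here the
EQ-5D-5L index, anchored at 1 = full health and allowed to go negative for
states worse than dead — from a non-preference instrument, here the FACT-B.
Observed utilities from five-level EQ-5D data are right-skewed with a point
mass at 1 (the ceiling): in the development cohort about a quarter of
respondents report full health. The ceiling breaks the homoscedastic
Gaussian assumptions of OLS and motivates the two alternative estimators.

## Estimators

**OLS.** Least squares on the observed utility. Coefficient covariance is
the classical σ̂²(X'X)⁻¹ with the unbiased residual variance; p-values are
two-tailed t-tests. The reported log-likelihood is the Gaussian likelihood
at the ML variance (RSS/n), and the parameter count k includes the residual
SD, so AIC/BIC are comparable across families.

**Tobit.** A latent Gaussian y* = x'β + ε, ε ~ N(0, σ²), observed as
min(y*, 1). Uncensored rows contribute log φ((y−x'β)/σ) − log σ; rows at
the bound contribute log Φ((x'β−1)/σ). The likelihood is maximised by BFGS
on (β, log σ) with an analytic gradient and an OLS warm start; convergence
requires the optimizer's gradient tolerance (1e−6) and failures are flagged
in the result, never silently returned. Standard errors come from the
observed information, computed by central finite differences of the
analytic gradient; the SE of σ uses the delta method from log σ. The
inverse Mills ratio is evaluated in log space (`log_ndtr`) for stability.
With no censored rows the likelihood is the OLS likelihood and the fit
reproduces OLS to optimizer precision (this is tested).

**Logistic / two-part.** The two-part model fits (1) a logistic regression
on the ceiling indicator 1{y = 1} by Newton–Raphson, and (2) OLS on the
rows with y < 1; both parts share one term set. Prediction is
p̂·1 + (1−p̂)·ŷ₂, which always lies between ŷ₂ and 1. Complete separation is
detected (diverging coefficients or perfect classification at extreme
linear indices) and raised as an error rather than returned as runaway
estimates. The conditional part is assumed to be plain OLS on the y < 1
rows; nothing more elaborate (e.g. a truncated-normal MLE) is claimed for
it.

**Prediction conventions.** Raw OLS predictions are not clamped by default
— a small fraction above 1 is reported rather than hidden (the "upper
bound %" of the prediction summary); `cap_at_1` is available for applied
use. Published Tobit sets predict via the latent index because their σ was
never published; the censored expectation
E[min(Y*,1)] = Φ(α)x'β − σφ(α) + (1−Φ(α)), α = (1−x'β)/σ, is available for
refit models or whenever a σ is attached. Part-1 coefficients of the
published two-part sets were printed as odds ratios (their clustering near
1 and intercepts of 0.00048 and 4.89e−06 admit no other coherent reading);
the registry stores the printed values and converts to log-odds at load
time, recording the declared scale.

## The specification ladder

Stage 1 uses the FACT-B total score; stage 2 all five subscales; stage 3
the subscales with two-tailed p < 0.10 at stage 2; stage 4 adds squared
terms of the stage-3 subscales; stage 5 adds their pairwise interactions.
Candidate squared/interaction terms are screened one-shot: the full
candidate set is fit once, survivors at p < 0.10 kept, and the model refit
— no stepwise iteration. Retention is strict (`p < 0.10`, not ≤). For the
two-part family, screening uses the conditional-part (OLS) p-values and the
surviving term set is shared by both parts, consistent with the published
two-part tables, where both parts always carry identical terms. p-values
are t-based for OLS and Wald-normal for Tobit and logistic fits.

## Goodness of fit and cross-validation

r² is the squared Pearson correlation between observed and predicted
values — well defined for all three families, unlike the OLS coefficient of
determination — and adjusted r² = 1 − ((n−1)/(n−p−1))(1−r²) with p the
predictor count excluding the intercept. RMSE and MAE are the usual root
mean square and mean absolute prediction errors. MAD is ambiguous in this
literature; the default is the mean absolute deviation of errors about the
mean error, with `about_median` and `median_absolute_error` selectable, and
every report records the definition used. AIC = −2lnL + 2k and
BIC = −2lnL + k·ln n, so BIC − AIC = k(ln n − 2) always.

Cross-validation partitions rows into k = 5 near-equal folds from a seeded
permutation (sizes differ by at most one), refits the fixed term set on
each training split — ladder screening is *not* re-run per fold — and
scores held-out MAE. An option stratifies folds on the ceiling indicator;
the default is simple random assignment.

**Linear equating.** Y = μ_Y + (σ_Y/σ_X)(X − μ_X), with X-moments from the
predictions and Y-moments from the observations. All SDs in the package use
the n−1 denominator, so equated predictions reproduce the observed mean and
SD exactly (to rounding), which is tested at 1e−12.

## Synthetic cohorts

The generator emulates the statistical structure the estimators must face:
correlated subscale totals (multivariate normal with exchangeable
correlation, rounded to integers and clipped to the instrument ranges), a
latent utility from a true coefficient set, and observed utility
min(latent + Gaussian noise, 1), floored at −0.391 (the worst value a
five-level tariff of this region assigns). A second mechanism draws the
ceiling explicitly (Bernoulli from a logistic index) plus a conditional
continuous part whose support stays below 1, so two-part recovery can be
tested without model mismatch.

`default_paperlike_config` fixes the study conditions: n = 446, subscale
means (22, 21, 17, 18, 26) with SD 5.3 and correlation 0.4 (total-score
mean ≈ 104, SD ≈ 18), the full published OLS polynomial with its intercept
raised by 0.045 as the true mapping, and noise SD 0.105. The intercept
shift is needed because the published curve, evaluated on these subscale
marginals, sits too low to reproduce the ~25% ceiling mass. These constants
were fixed once against the published descriptive envelopes (total mean
104 ± 5, utility mean 0.857 ± 0.03, ceiling 0.25 ± 0.05, Spearman
0.64 ± 0.10) and generated cohorts land inside all four across seeds.

What the generator does **not** emulate: the discrete 3125-state support of
real EQ-5D utilities (synthetic non-ceiling utilities are continuous), the
exact pairwise Spearman structure among subscales (only an exchangeable
correlation), floor clumping, and demographic/clinical covariates. Passing
tests on these cohorts therefore demonstrate estimator and pipeline
correctness under the generating assumptions, not clinical validity of the
published mapping on new populations.

## Instruments

FACT-B scoring reverse-scores negatively worded items (4 − value) so every
subscale points higher-is-better; subscale maxima are 28/28/24/28/40 and
the total 148. Which items are negatively worded is configuration data, not
code: the shipped default follows the standard FACIT orientation (PWB
negative; SWB and FWB positive; EWB all negative except the "satisfied with
coping" item; BCS mixed), and any custom `item,domain,polarity` CSV may be
supplied. Missing items are prorated (mean contribution × item count) when
at least half of a subscale's items were answered; proration can be
disabled, in which case any missing item is an error. Whether the
development study prorated is unknown; proration-on is the field's default
convention.

EQ-5D-5L profiles use canonical coding (1 = no problems). The reversed view
(6 − level, so 5 = no problems) exists because correlation analyses align
both instruments higher-is-better; it is an involution and never feeds the
tariff. Value sets are data: full-table or additive-decrement CSVs,
validated to anchor (1,1,1,1,1) at exactly 1 and never exceed 1. No real
tariff values ship with the package.

## Numerical and degenerate-input choices

- Quantiles (P10/P90 in prediction summaries) use inclusive linear
  interpolation, the numpy default; the convention is stated because
  published tables rarely specify theirs.
- Strictly-greater-than-1 defines the "upper bound %" (a prediction of
  exactly 1 is not an exceedance).
- Ceiling detection uses y ≥ 1 − 1e−9 to absorb float noise.
- Rank correlation uses mid-ranks (average ranks for ties).
- Singular designs, all-censored Tobit data, single-class logistic
  outcomes, empty prediction lists, constant series in correlations, zero
  predicted variance in equating, and uncovered value-set profiles all
  raise typed errors naming the offending component.
- Problem sizes in the test suite and acceptance script (n = 446 cohorts,
  n = 5000 recovery simulations, n = 20000 for the end-to-end Tobit
  recovery, 20-seed envelope sweeps) were chosen to make the statistical
  checks decisive at desk scale.

## Known limitations

The published development-cohort metric values (r² = 0.700, AIC = −705.106,
the cross-validated MAEs) depend on the original 446-patient dataset, which
is not deposited; the package reproduces the formulas, conventions and
pipeline, and verifies them on synthetic cohorts, but cannot regenerate
those specific numbers. The exact k the original analysis used inside AIC
for Tobit/TPM, its MAD formula, and whether its cross-validation refit the
ladder per fold are unstated; this package's choices (k includes σ where a
Gaussian likelihood is used; MAD about the mean error; fixed term sets in
CV) are documented above and configurable where meaningful.
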