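"""Re-derive the mapping on a synthetic cohort: the five-model ladder.

Generates a study-conditions cohort (n = 446: right-skewed utilities with a
~25% ceiling at 1, subscale totals in range, Spearman ~0.64 with utility),
fits the OLS specification ladder — total score; all domains; significant
domains; + squared terms; + interactions, each screened at two-tailed
p < 0.10 — and prints the goodness-of-fit table.
"""

import pandas as pd

from utilmap import build_ladder, default_paperlike_config, evaluate_fit, generate_cohort

cohort = generate_cohort(default_paperlike_config(seed=1))
data = cohort.dataset()
print(
    f"cohort: n={data.n}, FACT-B total mean {data.frame['total'].mean():.1f}, "
    f"utility mean {data.frame['utility'].mean():.3f}, "
    f"ceiling {100 * cohort.ceiling_fraction:.1f}%\n"
)

rows = []
for spec, fit in build_ladder(data, "ols"):
    report = evaluate_fit(fit, data)
    rows.append(
        {
            "model": fit.coefficients.model_id,
            "terms": len(spec.terms) - 1,
            "r2": round(report.r2, 3),
            "adj_r2": round(report.adj_r2, 3),
            "rmse": round(report.rmse, 3),
            "mae": round(report.mae, 3),
            "aic": round(report.aic, 1),
            "bic": round(report.bic, 1),
        }
    )
print(pd.DataFrame(rows).to_string(index=False))
print(
    "\nSquared and interaction terms (stages 4-5) buy most of the fit; "
    "lower RMSE/MAE/AIC/BIC and higher r2 indicate the better model."
)
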