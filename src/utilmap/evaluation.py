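"""Goodness-of-fit metrics and cross-validation for mapping models.

The metric suite mirrors standard utility-mapping practice: r-squared
(squared Pearson correlation of observed vs predicted — well defined for
all three families, unlike the OLS coefficient of determination), adjusted
r-squared 1 - ((n-1)/(n-p-1))(1-r^2), RMSE, MAD, MAE, and AIC/BIC in the
-2 log L convention.  Out-of-sample stability is assessed by seeded k-fold
cross-validation scored with the mean absolute error.

MAD is ambiguous in the literature; the default here is the mean absolute
deviation of prediction errors about the mean error, with the about-median
and median-absolute-error variants selectable.  Every report records which
definition was used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import EvaluationError
from .estimation import Dataset, Family, FitResult, ModelSpec, _fit
from .mapping import predict

MadDefinition = Literal["about_mean", "about_median", "median_absolute_error"]


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 3:
        raise EvaluationError("need equal-length series of at least 3 points")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise EvaluationError("correlation undefined for a constant series")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted r-squared: 1 - ((n-1)/(n-p-1)) (1-r^2).

    ``p`` is the number of predictors excluding the intercept.
    """
    if n <= p + 1:
        raise EvaluationError(f"n = {n} must exceed p + 1 = {p + 1}")
    return 1.0 - (n - 1) / (n - p - 1) * (1.0 - r2)


def error_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    mad_definition: MadDefinition = "about_mean",
) -> tuple[float, float, float]:
    """(RMSE, MAD, MAE) of errors e = observed - predicted."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise EvaluationError("need equal-length non-empty series")
    e = obs - pred
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    if mad_definition == "about_mean":
        mad = float(np.mean(np.abs(e - np.mean(e))))
    elif mad_definition == "about_median":
        mad = float(np.mean(np.abs(e - np.median(e))))
    elif mad_definition == "median_absolute_error":
        mad = float(np.median(np.abs(e)))
    else:
        raise EvaluationError(f"unknown MAD definition {mad_definition!r}")
    return rmse, mad, mae


def information_criteria(
    log_likelihood: float, k: int, n: int
) -> tuple[float, float]:
    """AIC = -2 ln L + 2k and BIC = -2 ln L + k ln n."""
    if k < 1 or n < 1:
        raise EvaluationError("k and n must be positive")
    aic = -2.0 * log_likelihood + 2.0 * k
    bic = -2.0 * log_likelihood + k * math.log(n)
    return aic, bic


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.size < 3:
        raise EvaluationError("need equal-length series of at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise EvaluationError("rank correlation undefined for a constant series")
    return float(stats.spearmanr(xa, ya).statistic)


@dataclass(frozen=True)
class MetricReport:
    """Full metric suite for one model on one dataset."""

    model_id: str
    r2: float
    adj_r2: float
    rmse: float
    mad: float
    mae: float
    aic: float
    bic: float
    n: int
    p: int  # predictors excluding intercept
    k: int  # estimated parameters including intercept (and sigma where used)
    mad_definition: MadDefinition = "about_mean"

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "mad": self.mad,
            "mae": self.mae,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "p": self.p,
            "k": self.k,
            "mad_definition": self.mad_definition,
        }


def evaluate_fit(
    fit: FitResult,
    data: Dataset,
    mad_definition: MadDefinition = "about_mean",
) -> MetricReport:
    """Score a fitted model on a dataset with the full metric suite.

    Predictions use the family defaults (raw OLS index, Tobit latent index,
    two-part composition).  AIC/BIC use the fit's own log-likelihood and are
    in-sample quantities; the error metrics apply to whatever dataset is
    passed, so out-of-sample scoring is possible.
    """
    pred = np.asarray(predict(fit.coefficients, data.frame))
    obs = data.utility
    r2 = r_squared(obs, pred)
    p = fit.n_predictors
    rmse, mad, mae = error_metrics(obs, pred, mad_definition)
    aic, bic = information_criteria(fit.log_likelihood, fit.k, fit.n)
    return MetricReport(
        model_id=fit.coefficients.model_id,
        r2=r2,
        adj_r2=adjusted_r2(r2, data.n, p),
        rmse=rmse,
        mad=mad,
        mae=mae,
        aic=aic,
        bic=bic,
        n=data.n,
        p=p,
        k=fit.k,
        mad_definition=mad_definition,
    )


@dataclass(frozen=True)
class CvReport:
    """Result of seeded k-fold cross-validation, scored by MAE."""

    k_folds: int
    seed: int
    fold_assignments: tuple[int, ...]
    fold_mae: tuple[float, ...]
    mean_mae: float
    stratified: bool = False

    def fold_sizes(self) -> list[int]:
        return list(np.bincount(np.asarray(self.fold_assignments)))


def kfold_cv(
    data: Dataset,
    spec: ModelSpec,
    family: Family | None = None,
    k: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> CvReport:
    """K-fold cross-validation of one model specification.

    Rows are randomly partitioned (seeded) into k near-equal folds; each fold
    is predicted by the model fit on the other k-1.  ``stratified=True``
    balances the ceiling indicator across folds.  The term set is fixed: the
    ladder's screening is *not* re-run per fold.
    """
    fam: Family = family or spec.family
    n = data.n
    if n < k:
        raise EvaluationError(f"n = {n} smaller than k = {k}")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if stratified:
        for cls in (0, 1):
            idx = np.flatnonzero(data.ceiling == cls)
            perm = rng.permutation(idx)
            assign[perm] = np.arange(len(perm)) % k
    else:
        perm = rng.permutation(n)
        # contiguous blocks of a random permutation: sizes differ by <= 1
        for f, chunk in enumerate(np.array_split(perm, k)):
            assign[chunk] = f

    fold_mae: list[float] = []
    for f in range(k):
        test_mask = assign == f
        try:
            fit = _fit(data.subset(~test_mask), spec, fam, f"cv_fold{f}")
        except Exception as exc:  # noqa: BLE001 - report names fold and cause
            raise EvaluationError(f"fold {f} fit failed: {exc}") from exc
        test = data.subset(test_mask)
        pred = np.asarray(predict(fit.coefficients, test.frame))
        fold_mae.append(float(np.mean(np.abs(test.utility - pred))))
    return CvReport(
        k_folds=k,
        seed=seed,
        fold_assignments=tuple(int(a) for a in assign),
        fold_mae=tuple(fold_mae),
        mean_mae=float(np.mean(fold_mae)),
        stratified=stratified,
    )
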