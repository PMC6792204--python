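"""Fitting mapping models from paired (FACT-B, utility) data.

Three estimators are provided, matching the three families used for
utility mapping in the presence of a ceiling at 1:

* **OLS** — ordinary least squares on the observed utility;
* **Tobit** — maximum likelihood for a latent Gaussian outcome right-censored
  at 1: uncensored rows contribute the Gaussian density, ceiling rows the
  upper-tail probability.  Optimised by quasi-Newton on (beta, log sigma)
  with an OLS warm start; standard errors come from the observed information
  (finite-difference Hessian of the analytic gradient);
* **Two-part model (TPM)** — a logistic regression for P(utility = 1)
  combined with OLS on the non-ceiling rows; prediction is
  p * 1 + (1 - p) * conditional mean.

``build_ladder`` reproduces the five-model specification ladder used in
utility-mapping studies: total score only; all five domains; domains
surviving a two-tailed p < 0.10 screen; plus squared terms of the surviving
domains (screened at p < 0.10); plus their pairwise interactions (same
screen).  Screening is one-shot: the full candidate set is fit once,
survivors kept, and the model refit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_ndtr

from .errors import EstimationError, LadderAbortError, SpecificationError
from .mapping import CoefficientSet, EquatingParams, Term, design_matrix

P_RETAIN = 0.10  # two-tailed screening threshold for the ladder
CEILING_TOL = 1e-9

Family = Literal["ols", "tobit", "tpm"]

DOMAIN_VARS = ("PWB", "SWB", "EWB", "FWB", "BCS")


@dataclass(frozen=True)
class Dataset:
    """Paired FACT-B scores and observed utilities.

    ``frame`` columns: pwb, swb, ewb, fwb, bcs, total, utility (lower-case).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.rename(columns=str.lower)
        needed = {"pwb", "swb", "ewb", "fwb", "bcs", "utility"}
        missing = sorted(needed - set(df.columns))
        if missing:
            raise SpecificationError(f"dataset missing columns {missing}")
        if "total" not in df.columns:
            df = df.assign(
                total=df[["pwb", "swb", "ewb", "fwb", "bcs"]].sum(axis=1)
            )
        if (df["utility"] > 1 + 1e-9).any():
            raise SpecificationError("observed utilities must not exceed 1")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def utility(self) -> np.ndarray:
        return self.frame["utility"].to_numpy(dtype=float)

    @property
    def ceiling(self) -> np.ndarray:
        """Indicator of rows at the utility ceiling of 1."""
        return (self.utility >= 1.0 - CEILING_TOL).astype(int)

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(self.frame.loc[np.asarray(mask, bool)].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ModelSpec:
    """A model's term structure (coefficients unset) plus its family."""

    terms: tuple[Term, ...]
    family: Family = "ols"
    ladder_stage: int | None = None

    def __post_init__(self) -> None:
        if sum(1 for t in self.terms if t.kind == "intercept") != 1:
            raise SpecificationError("spec must contain exactly one intercept")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)


def spec_stage1(family: Family = "ols") -> ModelSpec:
    return ModelSpec(
        (Term("intercept"), Term("linear", ("TOTAL",))), family, ladder_stage=1
    )


def spec_stage2(family: Family = "ols") -> ModelSpec:
    terms = (Term("intercept"),) + tuple(Term("linear", (v,)) for v in DOMAIN_VARS)
    return ModelSpec(terms, family, ladder_stage=2)


@dataclass(frozen=True)
class FitResult:
    """A fitted model: coefficients, uncertainty, and likelihood bookkeeping.

    ``k`` counts every estimated parameter, including the residual scale for
    Gaussian-likelihood families (OLS, Tobit) and both parts for the TPM.
    """

    coefficients: CoefficientSet
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    k: int
    n: int
    converged: bool
    sigma: float | None = None
    parts: dict[str, "FitResult"] = field(default_factory=dict)

    @property
    def n_predictors(self) -> int:
        """Predictor count excluding intercepts (and excluding sigma)."""
        return sum(
            sum(1 for t in terms if t.kind != "intercept")
            for terms in self.coefficients.parts.values()
        )


def _design(data: Dataset, terms: Sequence[Term]) -> np.ndarray:
    X = design_matrix(data.frame, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        labels = [t.label for t in terms]
        raise EstimationError(
            f"singular design matrix (rank {rank} < {X.shape[1]}); "
            f"collinear terms among {labels}"
        )
    return X


def _with_coefs(terms: Sequence[Term], beta: np.ndarray) -> tuple[Term, ...]:
    return tuple(
        Term(t.kind, t.variables, float(b)) for t, b in zip(terms, beta)
    )


def fit_ols(data: Dataset, spec: ModelSpec, model_id: str = "fit_ols") -> FitResult:
    """Ordinary least squares with classical t-test p-values.

    The Gaussian log-likelihood is evaluated at the ML variance (RSS/n) so
    that AIC/BIC are comparable across families; ``k`` therefore includes
    the residual SD as an estimated parameter.
    """
    y = data.utility
    X = _design(data, spec.terms)
    n, p = X.shape
    if n < p + 1:
        raise EstimationError(f"n = {n} too small for {p} coefficients")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2_hat = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sigma_ml = math.sqrt(rss / n)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma_ml**2) + 1.0)
    labels = [t.label for t in spec.terms]
    coefs = CoefficientSet(
        model_id=model_id,
        family="ols",
        parts={"main": _with_coefs(spec.terms, beta)},
        scale_sigma=sigma_ml,
    )
    return FitResult(
        coefficients=coefs,
        standard_errors=dict(zip(labels, se)),
        p_values=dict(zip(labels, pvals)),
        log_likelihood=loglik,
        k=p + 1,
        n=n,
        converged=True,
        sigma=sigma_ml,
    )


def _tobit_nll_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, cens: np.ndarray, upper: float
) -> tuple[float, np.ndarray]:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = math.exp(log_sigma)
    xb = X @ beta
    unc = ~cens
    e = y[unc] - xb[unc]
    # uncensored: Gaussian density; censored: upper-tail mass log Phi((xb-U)/sigma)
    ll_unc = -0.5 * math.log(2 * math.pi) - log_sigma - 0.5 * (e / sigma) ** 2
    z = (xb[cens] - upper) / sigma
    ll_cen = log_ndtr(z)
    nll = -(ll_unc.sum() + ll_cen.sum())

    g_beta = np.zeros(len(beta))
    g_beta += X[unc].T @ (e / sigma**2)
    # inverse Mills ratio phi(z)/Phi(z), computed in log space for stability
    mills = np.exp(
        -0.5 * z**2 - 0.5 * math.log(2 * math.pi) - log_ndtr(z)
    )
    g_beta += X[cens].T @ (mills / sigma)
    g_logsig = float(np.sum(-1.0 + (e / sigma) ** 2) + np.sum(mills * (-z)))
    return nll, -np.append(g_beta, g_logsig)


def fit_tobit(
    data: Dataset,
    spec: ModelSpec,
    upper: float = 1.0,
    model_id: str = "fit_tobit",
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> FitResult:
    """Upper-censored Gaussian regression by maximum likelihood.

    Rows at the bound contribute log(1 - Phi((upper - x'beta)/sigma)); the
    rest contribute the Gaussian log-density.  Wald (normal) p-values from
    the observed information.
    """
    y = data.utility
    X = _design(data, spec.terms)
    n, p = X.shape
    cens = y >= upper - CEILING_TOL
    if cens.all():
        raise EstimationError("all observations censored; model not identifiable")

    ols = fit_ols(data, spec)
    beta0 = np.array([t.coefficient for t in ols.coefficients.terms])
    theta0 = np.append(beta0, math.log(max(ols.sigma, 1e-3)))

    res = optimize.minimize(
        _tobit_nll_grad,
        theta0,
        args=(X, y, cens, upper),
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-4 * max(1.0, abs(res.fun)))

    # observed information: central finite differences of the analytic gradient
    dim = len(theta)
    H = np.zeros((dim, dim))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(dim):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _tobit_nll_grad(tp, X, y, cens, upper)
        _, gm = _tobit_nll_grad(tm, X, y, cens, upper)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((dim, dim), np.nan)
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    beta, sigma = theta[:-1], math.exp(theta[-1])
    se_beta = se[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se_beta
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    labels = [t.label for t in spec.terms]
    coefs = CoefficientSet(
        model_id=model_id,
        family="tobit",
        parts={"main": _with_coefs(spec.terms, beta)},
        scale_sigma=sigma,
        censor_upper=upper,
    )
    ses = dict(zip(labels, se_beta))
    ses["sigma"] = sigma * float(se[-1])  # delta method from log sigma
    return FitResult(
        coefficients=coefs,
        standard_errors=ses,
        p_values=dict(zip(labels, pvals)),
        log_likelihood=-float(res.fun),
        k=p + 1,
        n=n,
        converged=converged,
        sigma=sigma,
    )


def fit_logistic(
    data: Dataset,
    spec: ModelSpec,
    outcome: np.ndarray | None = None,
    model_id: str = "fit_logistic",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood logistic regression by Newton-Raphson (IRLS).

    ``outcome`` defaults to the ceiling indicator (utility == 1).  Complete
    separation is reported as an error rather than returning runaway
    estimates.
    """
    y = data.ceiling.astype(float) if outcome is None else np.asarray(outcome, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise SpecificationError("logistic outcome must be binary 0/1")
    if y.min() == y.max():
        raise EstimationError(
            "logistic regression needs both outcome classes present"
        )
    X = _design(data, spec.terms)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        if np.max(np.abs(eta)) > 500 or np.linalg.norm(beta) > 1e6:
            raise EstimationError(
                "logistic coefficients diverging: data are (quasi-)completely "
                "separated"
            )
        grad = X.T @ (y - mu)
        H = X.T @ (W[:, None] * X)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            raise EstimationError("singular Hessian in logistic fit") from None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise EstimationError(
            "logistic fit did not converge; possible complete separation"
        )
    eta = X @ beta
    if np.max(np.abs(eta[np.abs(eta) < np.inf])) > 30 and np.all(
        (expit(eta) > 0.5) == (y > 0.5)
    ):
        raise EstimationError("complete separation detected in logistic fit")
    mu = np.clip(expit(eta), 1e-15, 1 - 1e-15)
    cov = np.linalg.inv(X.T @ ((mu * (1 - mu))[:, None] * X))
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    labels = [t.label for t in spec.terms]
    coefs = CoefficientSet(
        model_id=model_id,
        family="tpm",
        parts={
            "part1": _with_coefs(spec.terms, beta),
            "part2": (Term("intercept", (), 0.0),),  # placeholder, see fit_tpm
        },
    )
    return FitResult(
        coefficients=coefs,
        standard_errors=dict(zip(labels, se)),
        p_values=dict(zip(labels, pvals)),
        log_likelihood=loglik,
        k=p,
        n=n,
        converged=True,
    )


def odds_ratios(fit: FitResult, part: str = "part1") -> dict[str, float]:
    """Odds-ratio view of logistic coefficients (exp(beta))."""
    return {
        t.label: math.exp(t.coefficient)
        for t in fit.coefficients.parts[part]
    }


def fit_tpm(data: Dataset, spec: ModelSpec, model_id: str = "fit_tpm") -> FitResult:
    """Two-part fit: logistic on the ceiling indicator + OLS on rows below 1.

    Both parts share the term structure of ``spec``.  The combined ``k`` sums
    both parts' parameters; the reported log-likelihood is their sum (the
    parts factorise).
    """
    cens = data.ceiling.astype(bool)
    if not cens.any() or cens.all():
        raise EstimationError(
            "two-part model needs both ceiling and non-ceiling rows"
        )
    part1 = fit_logistic(data, spec, model_id=model_id)
    part2 = fit_ols(data.subset(~cens), spec, model_id=model_id)
    coefs = CoefficientSet(
        model_id=model_id,
        family="tpm",
        parts={
            "part1": part1.coefficients.parts["part1"],
            "part2": part2.coefficients.terms,
        },
    )
    ses = {f"part1:{k}": v for k, v in part1.standard_errors.items()}
    ses.update({f"part2:{k}": v for k, v in part2.standard_errors.items()})
    ps = {f"part1:{k}": v for k, v in part1.p_values.items()}
    ps.update({f"part2:{k}": v for k, v in part2.p_values.items()})
    return FitResult(
        coefficients=coefs,
        standard_errors=ses,
        p_values=ps,
        log_likelihood=part1.log_likelihood + part2.log_likelihood,
        k=part1.k + part2.k,
        n=data.n,
        converged=part1.converged and part2.converged,
        sigma=part2.sigma,
        parts={"part1": part1, "part2": part2},
    )


def _fit(data: Dataset, spec: ModelSpec, family: Family, model_id: str) -> FitResult:
    if family == "ols":
        return fit_ols(data, spec, model_id)
    if family == "tobit":
        return fit_tobit(data, spec, model_id=model_id)
    if family == "tpm":
        return fit_tpm(data, spec, model_id)
    raise SpecificationError(f"unknown family {family!r}")


def _screen_pvalues(fit: FitResult, family: Family) -> dict[str, float]:
    # TPM terms are screened on the conditional (part-2) fit: the published
    # two-part models carry identical term sets in both parts.
    if family == "tpm":
        return {
            k.removeprefix("part2:"): v
            for k, v in fit.p_values.items()
            if k.startswith("part2:")
        }
    return dict(fit.p_values)


def screen_terms(
    candidates: Sequence[Term],
    p_values: dict[str, float],
    threshold: float = P_RETAIN,
) -> list[Term]:
    """Keep candidate terms with two-tailed p strictly below the threshold."""
    return [t for t in candidates if p_values.get(t.label, 1.0) < threshold]


def build_ladder(
    data: Dataset, family: Family = "ols"
) -> list[tuple[ModelSpec, FitResult]]:
    """Fit the five-stage specification ladder.

    Stage 1: total score.  Stage 2: all five domains.  Stage 3: domains with
    two-tailed p < 0.10 at stage 2.  Stage 4: stage 3 + squared terms of the
    stage-3 domains surviving a p < 0.10 screen.  Stage 5: stage 4 + pairwise
    interactions of the stage-3 domains surviving the same screen.
    """
    out: list[tuple[ModelSpec, FitResult]] = []

    s1 = spec_stage1(family)
    out.append((s1, _fit(data, s1, family, f"{family.upper()}1")))

    s2 = spec_stage2(family)
    fit2 = _fit(data, s2, family, f"{family.upper()}2")
    out.append((s2, fit2))

    p2 = _screen_pvalues(fit2, family)
    kept = [
        t.variables[0]
        for t in screen_terms([Term("linear", (v,)) for v in DOMAIN_VARS], p2)
    ]
    if not kept:
        raise LadderAbortError(
            f"no domain significant at p < {P_RETAIN} in stage 2; ladder aborted"
        )
    s3 = ModelSpec(
        (Term("intercept"),) + tuple(Term("linear", (v,)) for v in kept),
        family,
        ladder_stage=3,
    )
    out.append((s3, _fit(data, s3, family, f"{family.upper()}3")))

    # stage 4: screen squared terms of the surviving domains, one-shot
    sq_candidates = [Term("squared", (v,)) for v in kept]
    screen4 = ModelSpec(s3.terms + tuple(sq_candidates), family)
    fit_s4 = _fit(data, screen4, family, "screen4")
    kept_sq = screen_terms(sq_candidates, _screen_pvalues(fit_s4, family))
    s4 = ModelSpec(s3.terms + tuple(kept_sq), family, ladder_stage=4)
    out.append((s4, _fit(data, s4, family, f"{family.upper()}4")))

    # stage 5: add pairwise interactions of the surviving domains, same screen
    int_candidates = [
        Term("interaction", pair) for pair in itertools.combinations(kept, 2)
    ]
    screen5 = ModelSpec(s4.terms + tuple(int_candidates), family)
    fit_s5 = _fit(data, screen5, family, "screen5")
    kept_int = screen_terms(int_candidates, _screen_pvalues(fit_s5, family))
    s5 = ModelSpec(s4.terms + tuple(kept_int), family, ladder_stage=5)
    out.append((s5, _fit(data, s5, family, f"{family.upper()}5")))
    return out


def estimate_equating(
    observed: Sequence[float] | np.ndarray, predicted: Sequence[float] | np.ndarray
) -> EquatingParams:
    """Estimate linear-equating parameters from paired series.

    X-moments come from the predictions, Y-moments from the observations;
    sample SDs use the n-1 denominator so the equated series reproduces the
    observed mean and SD exactly.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 2:
        raise EstimationError("need equal-length series with at least 2 points")
    sigma_x = float(np.std(pred, ddof=1))
    if sigma_x <= 0:
        raise EstimationError("predicted series has zero variance")
    return EquatingParams(
        mu_x=float(np.mean(pred)),
        sigma_x=sigma_x,
        mu_y=float(np.mean(obs)),
        sigma_y=float(np.std(obs, ddof=1)),
    )
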