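"""Published coefficient sets and utility prediction from FACT-B scores.

Nine published mapping models are shipped in a versioned registry CSV:
``OLS1``-``OLS5`` (a specification ladder from the total score up to domain
scores with squared and interaction terms), ``TOBIT4``/``TOBIT5`` (upper-
censored regression) and ``TPM4``/``TPM5`` (two-part: logistic ceiling model
plus conditional linear model on PWB, FWB, BCS).

Prediction conventions
----------------------
* OLS predictions are raw linear-index values and are *not* clamped by
  default: the source study reports a small fraction of predictions above 1
  rather than capping them.  ``clamp="cap_at_1"`` is offered for applied use.
* Published Tobit sets predict via the latent index, because the residual
  scale sigma was not published; the censored-expectation rule
  ``E[min(Y*, 1)]`` is available whenever a sigma is supplied (e.g. for
  models refit in :mod:`utilmap.estimation`).
* Two-part part-1 coefficients were published as odds ratios; the registry
  stores them as printed and converts to log-odds at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .errors import RegistryError, SpecificationError, UtilmapError
from .instruments import FactBScores

REGISTRY_VERSION = "1.0"

VARIABLES: tuple[str, ...] = ("PWB", "SWB", "EWB", "FWB", "BCS", "TOTAL")

TermKind = Literal["intercept", "linear", "squared", "interaction"]


@dataclass(frozen=True)
class Term:
    """One model term: intercept, linear, squared or pairwise interaction."""

    kind: TermKind
    variables: tuple[str, ...] = ()
    coefficient: float | None = None

    def __post_init__(self) -> None:
        expected = {"intercept": 0, "linear": 1, "squared": 1, "interaction": 2}
        if self.kind not in expected:
            raise SpecificationError(f"unknown term kind {self.kind!r}")
        if len(self.variables) != expected[self.kind]:
            raise SpecificationError(
                f"{self.kind} term takes {expected[self.kind]} variable(s), "
                f"got {self.variables}"
            )
        if self.kind == "interaction" and self.variables[0] == self.variables[1]:
            raise SpecificationError("interaction variables must be distinct")
        for v in self.variables:
            if v not in VARIABLES:
                raise SpecificationError(
                    f"unknown variable {v!r}; valid: {VARIABLES}"
                )

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "const"
        if self.kind == "linear":
            return self.variables[0]
        if self.kind == "squared":
            return f"{self.variables[0]}^2"
        return "x".join(self.variables)


@dataclass(frozen=True)
class CoefficientSet:
    """A complete fitted or published mapping model.

    ``parts`` holds the term lists: key ``"main"`` for OLS/Tobit models,
    ``"part1"`` (log-odds scale) and ``"part2"`` for two-part models.
    ``scale_sigma`` is the Tobit residual SD when known.
    """

    model_id: str
    family: Literal["ols", "tobit", "tpm"]
    parts: Mapping[str, tuple[Term, ...]]
    scale_sigma: float | None = None
    censor_upper: float = 1.0
    part1_published_scale: str | None = None  # e.g. "odds_ratio"

    def __post_init__(self) -> None:
        expected_parts = {"tpm": {"part1", "part2"}}.get(self.family, {"main"})
        if set(self.parts) != expected_parts:
            raise SpecificationError(
                f"{self.family} model needs parts {sorted(expected_parts)}, "
                f"got {sorted(self.parts)}"
            )
        for name, terms in self.parts.items():
            n_int = sum(1 for t in terms if t.kind == "intercept")
            if n_int != 1:
                raise SpecificationError(
                    f"part {name!r} must contain exactly one intercept, got {n_int}"
                )

    @property
    def terms(self) -> tuple[Term, ...]:
        """Term list of a single-part (OLS/Tobit) model."""
        if self.family == "tpm":
            raise SpecificationError("two-part model: use parts['part1'/'part2']")
        return tuple(self.parts["main"])

    def n_parameters(self) -> int:
        k = sum(len(t) for t in self.parts.values())
        if self.family in ("ols", "tobit") and self.scale_sigma is not None:
            k += 1
        return k


_REGISTRY_CACHE: dict[str, CoefficientSet] | None = None


def _load_registry() -> dict[str, CoefficientSet]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is not None:
        return _REGISTRY_CACHE
    ref = resources.files("utilmap").joinpath("data/published_coefficients.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    sets: dict[str, CoefficientSet] = {}
    for model_id, grp in df.groupby("model_id", sort=False):
        parts: dict[str, tuple[Term, ...]] = {}
        part1_scale = None
        for part, pgrp in grp.groupby("part", sort=False):
            terms = []
            for r in pgrp.itertuples():
                coef = float(r.coefficient)
                if r.scale == "odds_ratio":
                    # printed as exp(beta); store the log-odds coefficient
                    coef = math.log(coef)
                    part1_scale = "odds_ratio"
                variables = tuple(
                    v for v in (r.var1, r.var2) if isinstance(v, str) and v
                )
                terms.append(Term(r.term_kind, variables, coef))
            parts[str(part)] = tuple(terms)
        family = "ols" if model_id.startswith("OLS") else (
            "tobit" if model_id.startswith("TOBIT") else "tpm"
        )
        sets[str(model_id)] = CoefficientSet(
            model_id=str(model_id),
            family=family,  # type: ignore[arg-type]
            parts=parts,
            part1_published_scale=part1_scale,
        )
    _REGISTRY_CACHE = sets
    return sets


def registry_ids() -> tuple[str, ...]:
    return tuple(_load_registry())


def published_coefficients(model_id: str) -> CoefficientSet:
    """Return one of the nine published coefficient sets by id.

    Valid ids: OLS1..OLS5, TOBIT4, TOBIT5, TPM4, TPM5.
    """
    reg = _load_registry()
    try:
        return reg[model_id]
    except KeyError:
        raise RegistryError(
            f"unknown model id {model_id!r}; valid ids: {', '.join(reg)}"
        ) from None


ScoresLike = "FactBScores | pd.DataFrame"


def _scores_frame(scores: FactBScores | pd.DataFrame) -> pd.DataFrame:
    if isinstance(scores, FactBScores):
        return pd.DataFrame([scores.as_dict()])
    df = scores.rename(columns=str.lower)
    cols = {"pwb", "swb", "ewb", "fwb", "bcs"}
    if not cols.issubset(df.columns):
        missing = sorted(cols - set(df.columns))
        raise SpecificationError(f"scores frame missing columns {missing}")
    out = df[["pwb", "swb", "ewb", "fwb", "bcs"]].astype(float).copy()
    out.columns = ["PWB", "SWB", "EWB", "FWB", "BCS"]
    out["TOTAL"] = (
        df["total"].astype(float)
        if "total" in df.columns
        else out.sum(axis=1)
    )
    return out


def design_matrix(
    scores: FactBScores | pd.DataFrame, terms: Sequence[Term]
) -> np.ndarray:
    """Stack term features row-wise; intercept terms contribute a 1 column."""
    frame = _scores_frame(scores)
    cols = []
    for t in terms:
        if t.kind == "intercept":
            cols.append(np.ones(len(frame)))
        elif t.kind == "linear":
            cols.append(frame[t.variables[0]].to_numpy())
        elif t.kind == "squared":
            cols.append(frame[t.variables[0]].to_numpy() ** 2)
        else:
            cols.append(
                frame[t.variables[0]].to_numpy() * frame[t.variables[1]].to_numpy()
            )
    return np.column_stack(cols)


def build_features(scores: FactBScores, terms: Sequence[Term]) -> np.ndarray:
    """Feature vector for one respondent, ordered as the term list."""
    return design_matrix(scores, terms)[0]


def _linear_index(
    terms: Sequence[Term], scores: FactBScores | pd.DataFrame
) -> np.ndarray:
    coefs = []
    for t in terms:
        if t.coefficient is None:
            raise SpecificationError(f"term {t.label} has no coefficient")
        coefs.append(t.coefficient)
    return design_matrix(scores, terms) @ np.asarray(coefs)


def _maybe_scalar(values: np.ndarray, scores) -> float | np.ndarray:
    if isinstance(scores, FactBScores):
        return float(values[0])
    return values


def predict_linear(
    coef: CoefficientSet,
    scores: FactBScores | pd.DataFrame,
    clamp: Literal["none", "cap_at_1"] = "none",
) -> float | np.ndarray:
    """Linear-index prediction (OLS; also the Tobit latent index)."""
    if coef.family == "tpm":
        raise SpecificationError("use predict_tpm for two-part models")
    xb = _linear_index(coef.parts["main"], scores)
    if clamp == "cap_at_1":
        xb = np.minimum(xb, 1.0)
    elif clamp != "none":
        raise SpecificationError(f"unknown clamp policy {clamp!r}")
    return _maybe_scalar(xb, scores)


def predict_tobit(
    coef: CoefficientSet,
    scores: FactBScores | pd.DataFrame,
    mode: Literal["latent", "censored_expectation"] = "latent",
) -> float | np.ndarray:
    """Tobit prediction.

    ``latent`` returns the linear index x'beta.  ``censored_expectation``
    returns E[min(Y*, U)] = Phi(a) x'beta - sigma phi(a) + U (1 - Phi(a))
    with a = (U - x'beta)/sigma, and requires ``scale_sigma``.
    """
    if coef.family != "tobit":
        raise SpecificationError(f"{coef.model_id} is not a tobit model")
    xb = _linear_index(coef.parts["main"], scores)
    if mode == "latent":
        return _maybe_scalar(xb, scores)
    if mode != "censored_expectation":
        raise SpecificationError(f"unknown tobit mode {mode!r}")
    if coef.scale_sigma is None:
        raise UtilmapError(
            f"{coef.model_id}: censored_expectation requires scale_sigma, "
            "which is not available (not published); use mode='latent'"
        )
    sigma = coef.scale_sigma
    upper = coef.censor_upper
    if sigma == 0:
        out = np.minimum(xb, upper)
    else:
        alpha = (upper - xb) / sigma
        phi = np.exp(-0.5 * alpha**2) / math.sqrt(2 * math.pi)
        out = ndtr(alpha) * xb - sigma * phi + upper * (1.0 - ndtr(alpha))
    return _maybe_scalar(out, scores)


def predict_tpm(
    coef: CoefficientSet, scores: FactBScores | pd.DataFrame
) -> float | np.ndarray:
    """Two-part prediction: p_ceiling * 1 + (1 - p_ceiling) * conditional mean."""
    if coef.family != "tpm":
        raise SpecificationError(f"{coef.model_id} is not a two-part model")
    eta = _linear_index(coef.parts["part1"], scores)
    p = expit(eta)
    y2 = _linear_index(coef.parts["part2"], scores)
    return _maybe_scalar(p * coef.censor_upper + (1.0 - p) * y2, scores)


def predict(
    coef: CoefficientSet,
    scores: FactBScores | pd.DataFrame,
    clamp: Literal["none", "cap_at_1"] = "none",
    tobit_mode: Literal["latent", "censored_expectation"] = "latent",
) -> float | np.ndarray:
    """Family-dispatching prediction with the package's default conventions."""
    if coef.family == "ols":
        return predict_linear(coef, scores, clamp=clamp)
    if coef.family == "tobit":
        out = predict_tobit(coef, scores, mode=tobit_mode)
    else:
        out = predict_tpm(coef, scores)
    if clamp == "cap_at_1":
        out = np.minimum(out, 1.0) if not np.isscalar(out) else min(out, 1.0)
    return out


@dataclass(frozen=True)
class EquatingParams:
    """Linear-equating parameters: moments of predicted (X) and observed (Y)."""

    mu_x: float
    sigma_x: float
    mu_y: float
    sigma_y: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise UtilmapError("equating requires sigma_x > 0 and sigma_y > 0")


def equate(
    x: float | np.ndarray | Sequence[float], params: EquatingParams
) -> float | np.ndarray:
    """Linear equating: Y = mu_Y + (sigma_Y / sigma_X) (X - mu_X).

    Rescales predictions to share the observed scores' mean and SD, the
    standard correction for regression to the mean in score linking.
    """
    arr = np.asarray(x, dtype=float)
    out = params.mu_y + (params.sigma_y / params.sigma_x) * (arr - params.mu_x)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class PredictionSummary:
    """Descriptive summary of a utility series, as reported for model checks."""

    mean: float
    sd: float
    min: float
    p10: float
    median: float
    p90: float
    max: float
    upper_bound_pct: float
    n: int = 0

    def __post_init__(self) -> None:
        q = (self.min, self.p10, self.median, self.p90, self.max)
        if any(a > b + 1e-12 for a, b in zip(q, q[1:])):
            raise UtilmapError(f"quantiles out of order: {q}")


def summarize_predictions(predictions: Sequence[float] | np.ndarray) -> PredictionSummary:
    """Mean/SD, min, P10, median, P90, max and % of predictions above 1.

    SD uses the n-1 denominator; quantiles use linear interpolation.
    "Upper bound" counts predictions strictly greater than 1 — the share of
    raw linear predictions escaping the utility scale's ceiling.
    """
    arr = np.asarray(predictions, dtype=float)
    if arr.size == 0:
        raise UtilmapError("cannot summarize an empty prediction list")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return PredictionSummary(
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        p10=float(np.quantile(arr, 0.10)),
        median=float(np.quantile(arr, 0.50)),
        p90=float(np.quantile(arr, 0.90)),
        max=float(np.max(arr)),
        upper_bound_pct=float(np.mean(arr > 1.0) * 100.0),
        n=int(arr.size),
    )


def with_sigma(coef: CoefficientSet, sigma: float) -> CoefficientSet:
    """Attach a residual scale to a (Tobit) coefficient set."""
    return replace(coef, scale_sigma=float(sigma))
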