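"""Estimators: OLS, censored-normal (Tobit) MLE, logistic, two-part, ladder."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from utilmap import (
    Dataset,
    EstimationError,
    ModelSpec,
    Term,
    build_ladder,
    default_paperlike_config,
    estimate_equating,
    equate,
    fit_logistic,
    fit_ols,
    fit_tobit,
    fit_tpm,
    generate_cohort,
    spec_stage2,
    two_part_config,
)
from utilmap.estimation import screen_terms


def make_dataset(rng, n, utility_fn, noise_sd=0.0, censor=False):
    frame = pd.DataFrame(
        {
            "pwb": rng.integers(0, 29, n),
            "swb": rng.integers(0, 29, n),
            "ewb": rng.integers(0, 25, n),
            "fwb": rng.integers(0, 29, n),
            "bcs": rng.integers(0, 41, n),
        }
    )
    frame["total"] = frame.sum(axis=1)
    y = utility_fn(frame) + rng.normal(0, noise_sd, n)
    frame["utility"] = np.minimum(y, 1.0) if censor else np.minimum(y, 1.0 - 1e-6)
    return Dataset(frame)


def coef_dict(fit):
    return {t.label: t.coefficient for t in fit.coefficients.parts[
        "main" if fit.coefficients.family != "tpm" else "part2"
    ]}


PWB_SPEC = ModelSpec((Term("intercept"), Term("linear", ("PWB",))))


class TestOls:
    def test_noiseless_linear_data_recovered_to_machine_precision(self, rng):
        data = make_dataset(rng, 50, lambda f: 0.1 + 0.02 * f["pwb"] - 0.3)
        fit = fit_ols(data, PWB_SPEC)
        cd = coef_dict(fit)
        assert cd["const"] == pytest.approx(-0.2, abs=1e-12)
        assert cd["PWB"] == pytest.approx(0.02, abs=1e-12)

    def test_residuals_orthogonal_to_design_columns(self, rng):
        data = make_dataset(rng, 80, lambda f: 0.5 + 0.003 * f["total"] - 0.5, 0.1)
        spec = spec_stage2()
        fit = fit_ols(data, spec)
        from utilmap.mapping import design_matrix

        X = design_matrix(data.frame, spec.terms)
        beta = np.array(list(coef_dict(fit).values()))
        resid = data.utility - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_random_problem_matches_pseudo_inverse_oracle(self, rng):
        data = make_dataset(rng, 30, lambda f: 0.2 + 0.01 * f["pwb"] - 0.2, 0.2)
        spec = ModelSpec(
            (
                Term("intercept"),
                Term("linear", ("PWB",)),
                Term("linear", ("EWB",)),
                Term("squared", ("BCS",)),
            )
        )
        fit = fit_ols(data, spec)
        X = np.column_stack(
            [
                np.ones(30),
                data.frame["pwb"],
                data.frame["ewb"],
                data.frame["bcs"] ** 2,
            ]
        )
        oracle = np.linalg.pinv(X) @ data.utility
        got = np.array(list(coef_dict(fit).values()))
        assert np.max(np.abs(got - oracle)) < 1e-8

    def test_agrees_with_statsmodels_reference(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        data = make_dataset(rng, 120, lambda f: 0.4 + 0.01 * f["pwb"] - 0.3, 0.15)
        spec = spec_stage2()
        fit = fit_ols(data, spec)
        from utilmap.mapping import design_matrix

        X = design_matrix(data.frame, spec.terms)
        ref = sm.OLS(data.utility, X).fit()
        assert np.allclose(list(coef_dict(fit).values()), ref.params, atol=1e-10)
        assert np.allclose(list(fit.p_values.values()), ref.pvalues, atol=1e-10)

    def test_collinear_terms_reported(self, rng):
        data = make_dataset(rng, 40, lambda f: 0.01 * f["pwb"], 0.1)
        spec = ModelSpec(
            (
                Term("intercept"),
                Term("linear", ("PWB",)),
                Term("linear", ("PWB",)),
            )
        )
        with pytest.raises(EstimationError, match="PWB"):
            fit_ols(data, spec)


class TestTobit:
    def test_uncensored_data_reduces_to_ols(self, rng):
        data = make_dataset(rng, 300, lambda f: 0.2 + 0.01 * f["pwb"] - 0.2, 0.1)
        assert data.ceiling.sum() == 0
        ols = fit_ols(data, PWB_SPEC)
        tob = fit_tobit(data, PWB_SPEC)
        for label in ("const", "PWB"):
            assert coef_dict(tob)[label] == pytest.approx(
                coef_dict(ols)[label], abs=1e-6
            )
        assert tob.sigma == pytest.approx(ols.sigma, abs=1e-6)

    def test_recovers_true_parameters_on_censored_simulation(self, rng):
        # truth: y* = 0.6 + 0.01 PWB + N(0, 0.1^2), observed min(y*, 1)
        data = make_dataset(
            rng, 5000, lambda f: 0.6 + 0.01 * f["pwb"], 0.1, censor=True
        )
        assert 0.005 < data.ceiling.mean() < 0.6
        fit = fit_tobit(data, PWB_SPEC)
        truth = {"const": 0.6, "PWB": 0.01}
        for label, true_val in truth.items():
            err = abs(coef_dict(fit)[label] - true_val)
            assert err < 3 * fit.standard_errors[label]
        assert abs(fit.sigma - 0.1) < 3 * fit.standard_errors["sigma"]

    def test_loglik_is_locally_optimal(self, rng):
        from utilmap.estimation import _tobit_nll_grad
        from utilmap.mapping import design_matrix

        data = make_dataset(
            rng, 500, lambda f: 0.7 + 0.01 * f["pwb"], 0.1, censor=True
        )
        fit = fit_tobit(data, PWB_SPEC)
        X = design_matrix(data.frame, PWB_SPEC.terms)
        cens = data.ceiling.astype(bool)
        theta_hat = np.append(
            list(coef_dict(fit).values()), np.log(fit.sigma)
        )
        nll_hat, _ = _tobit_nll_grad(theta_hat, X, data.utility, cens, 1.0)
        for j in range(len(theta_hat)):
            for delta in (-0.01, 0.01):
                theta = theta_hat.copy()
                theta[j] += delta
                nll, _ = _tobit_nll_grad(theta, X, data.utility, cens, 1.0)
                assert nll >= nll_hat - 1e-9

    def test_approaches_ols_as_censoring_vanishes(self, rng):
        diffs = []
        # intercepts chosen so the ceiling fractions are ~0%, ~1%, ~6%
        for intercept, censor in [(0.55, False), (0.62, True), (0.70, True)]:
            data = make_dataset(
                rng, 2000, lambda f: intercept + 0.008 * f["pwb"], 0.1, censor=censor
            )
            frac = data.ceiling.mean()
            ols = fit_ols(data, PWB_SPEC)
            tob = fit_tobit(data, PWB_SPEC)
            diffs.append(
                (frac, abs(coef_dict(tob)["const"] - coef_dict(ols)["const"]))
            )
        fracs, ds = zip(*diffs)
        assert fracs[0] == 0 and ds[0] < 1e-6
        assert ds[0] <= ds[1] <= ds[2]

    def test_fully_censored_data_not_identifiable(self):
        frame = pd.DataFrame(
            {c: np.arange(20) % 5 for c in ("pwb", "swb", "ewb", "fwb", "bcs")}
        )
        frame["utility"] = 1.0
        with pytest.raises(EstimationError, match="censored"):
            fit_tobit(Dataset(frame), PWB_SPEC)


class TestLogistic:
    def test_intercept_only_on_balanced_ceiling_gives_zero_log_odds(self):
        frame = pd.DataFrame(
            {c: np.arange(40) % 7 for c in ("pwb", "swb", "ewb", "fwb", "bcs")}
        )
        frame["utility"] = np.where(np.arange(40) % 2 == 0, 1.0, 0.5)
        fit = fit_logistic(Dataset(frame), ModelSpec((Term("intercept"),)))
        assert fit.coefficients.parts["part1"][0].coefficient == pytest.approx(
            0.0, abs=1e-8
        )

    def test_recovers_true_parameters_on_simulated_data(self, rng):
        n = 5000
        frame = pd.DataFrame(
            {
                "pwb": rng.integers(0, 29, n),
                "swb": 0, "ewb": 0, "fwb": 0, "bcs": 0,
            }
        )
        eta = -2.0 + 0.1 * frame["pwb"].to_numpy()
        y01 = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        frame["utility"] = np.where(y01 == 1, 1.0, 0.5)
        fit = fit_logistic(Dataset(frame), PWB_SPEC)
        by = {t.label: t.coefficient for t in fit.coefficients.parts["part1"]}
        assert abs(by["const"] - (-2.0)) < 3 * fit.standard_errors["const"]
        assert abs(by["PWB"] - 0.1) < 3 * fit.standard_errors["PWB"]

    def test_mean_fitted_probability_equals_ceiling_fraction(self, rng):
        data = generate_cohort(default_paperlike_config(seed=5)).dataset()
        fit = fit_logistic(data, spec_stage2())
        from utilmap.mapping import design_matrix

        X = design_matrix(data.frame, spec_stage2().terms)
        beta = np.array(
            [t.coefficient for t in fit.coefficients.parts["part1"]]
        )
        probs = 1 / (1 + np.exp(-(X @ beta)))
        assert probs.mean() == pytest.approx(data.ceiling.mean(), abs=1e-8)

    def test_complete_separation_is_an_error_not_runaway_estimates(self, rng):
        n = 200
        frame = pd.DataFrame(
            {
                "pwb": rng.integers(0, 29, n),
                "swb": 0, "ewb": 0, "fwb": 0, "bcs": 0,
            }
        )
        frame["utility"] = np.where(frame["pwb"] > 14, 1.0, 0.5)
        with pytest.raises(EstimationError, match="separat"):
            fit_logistic(Dataset(frame), PWB_SPEC)

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame(
            {c: np.arange(20) % 5 for c in ("pwb", "swb", "ewb", "fwb", "bcs")}
        )
        frame["utility"] = 0.5
        with pytest.raises(EstimationError, match="both"):
            fit_logistic(Dataset(frame), PWB_SPEC)


class TestTwoPart:
    def test_no_ceiling_rows_is_an_error(self, rng):
        data = make_dataset(rng, 100, lambda f: 0.3 + 0.005 * f["pwb"], 0.05)
        with pytest.raises(EstimationError, match="ceiling"):
            fit_tpm(data, PWB_SPEC)

    def test_part2_rowcount_is_the_non_ceiling_partition(self):
        data = generate_cohort(default_paperlike_config(seed=9)).dataset()
        fit = fit_tpm(data, spec_stage2("tpm"))
        assert fit.parts["part2"].n == data.n - data.ceiling.sum()

    def test_both_parts_recover_truth_on_two_part_generated_data(self):
        cfg = two_part_config(n=5000, seed=21)
        data = generate_cohort(cfg).dataset()
        spec = ModelSpec(
            (
                Term("intercept"),
                Term("linear", ("PWB",)),
                Term("linear", ("FWB",)),
                Term("linear", ("BCS",)),
            ),
            family="tpm",
        )
        fit = fit_tpm(data, spec)
        true1 = {t.label: t.coefficient for t in cfg.coefficients.parts["part1"]}
        true2 = {t.label: t.coefficient for t in cfg.coefficients.parts["part2"]}
        got1 = {t.label: t.coefficient for t in fit.coefficients.parts["part1"]}
        got2 = {t.label: t.coefficient for t in fit.coefficients.parts["part2"]}
        for label, tv in true1.items():
            assert abs(got1[label] - tv) < 3 * fit.standard_errors[f"part1:{label}"]
        for label, tv in true2.items():
            assert abs(got2[label] - tv) < 3 * fit.standard_errors[f"part2:{label}"]


class TestLadder:
    def test_retention_threshold_is_strict_at_0p10(self):
        candidates = [Term("linear", ("PWB",)), Term("linear", ("SWB",))]
        kept = screen_terms(candidates, {"PWB": 0.0999, "SWB": 0.1001})
        assert [t.label for t in kept] == ["PWB"]

    def test_null_domain_absent_from_stage3_in_most_replicates(self):
        # SWB's true coefficient is zero in the generating model
        absent = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = dataclasses.replace(default_paperlike_config(seed=seed), n=2000)
            ladder = build_ladder(generate_cohort(cfg).dataset(), "ols")
            stage3 = ladder[2][0]
            if "SWB" not in stage3.labels:
                absent += 1
        assert absent >= 0.95 * n_rep

    def test_stage_nesting_and_structure(self, paperlike_dataset):
        ladder = build_ladder(paperlike_dataset, "ols")
        specs = [spec for spec, _ in ladder]
        assert [s.ladder_stage for s in specs] == [1, 2, 3, 4, 5]
        assert specs[0].labels == ("const", "TOTAL")
        assert set(specs[1].labels) == {"const", "PWB", "SWB", "EWB", "FWB", "BCS"}
        assert set(specs[2].labels) <= set(specs[1].labels)
        assert set(specs[3].labels) >= set(specs[2].labels)
        assert set(specs[4].labels) >= set(specs[3].labels)

    def test_ladder_is_deterministic(self, paperlike_dataset):
        first = build_ladder(paperlike_dataset, "ols")
        second = build_ladder(paperlike_dataset, "ols")
        for (s1, f1), (s2, f2) in zip(first, second):
            assert s1.labels == s2.labels
            assert coef_dict(f1) == coef_dict(f2)

    def test_tpm_ladder_shares_terms_between_parts(self, paperlike_dataset):
        ladder = build_ladder(paperlike_dataset, "tpm")
        for _, fit in ladder:
            labels1 = [t.label for t in fit.coefficients.parts["part1"]]
            labels2 = [t.label for t in fit.coefficients.parts["part2"]]
            assert labels1 == labels2


class TestEquatingEstimation:
    def test_identity_when_series_equal(self, rng):
        x = rng.normal(0.8, 0.15, 100)
        p = estimate_equating(x, x)
        assert p.mu_x == p.mu_y and p.sigma_x == p.sigma_y

    def test_moment_parameters_match_inputs(self, rng):
        obs = rng.normal(0.857, 0.193, 446)
        pred = rng.normal(0.857, 0.161, 446)
        p = estimate_equating(obs, pred)
        assert p.mu_x == pytest.approx(pred.mean())
        assert p.sigma_x == pytest.approx(pred.std(ddof=1))
        assert p.mu_y == pytest.approx(obs.mean())
        assert p.sigma_y == pytest.approx(obs.std(ddof=1))

    def test_equated_series_reproduces_observed_moments_exactly(self, rng):
        obs = rng.normal(0.85, 0.19, 300)
        pred = rng.normal(0.85, 0.16, 300)
        p = estimate_equating(obs, pred)
        eq = equate(pred, p)
        assert eq.mean() == pytest.approx(obs.mean(), abs=1e-12)
        assert eq.std(ddof=1) == pytest.approx(obs.std(ddof=1), abs=1e-12)

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(EstimationError):
            estimate_equating([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])


class TestEstimatorConsistency:
    def test_rmse_shrinks_with_sample_size(self):
        rmses = []
        for n in (200, 1000, 5000):
            errs = []
            for rep in range(15):
                r = np.random.default_rng(1000 * n + rep)
                frame = pd.DataFrame(
                    {
                        "pwb": r.integers(0, 29, n),
                        "swb": 0, "ewb": 0, "fwb": 0, "bcs": 0,
                    }
                )
                frame["utility"] = np.minimum(
                    0.3 + 0.01 * frame["pwb"] + r.normal(0, 0.1, n), 1.0
                )
                fit = fit_ols(Dataset(frame), PWB_SPEC)
                errs.append(coef_dict(fit)["PWB"] - 0.01)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_large_cohort_recovery_of_the_generating_model(self):
        # the censored generator's true family is Tobit: refit it at n = 20000
        cfg = dataclasses.replace(default_paperlike_config(seed=13), n=20000)
        data = generate_cohort(cfg).dataset()
        truth = {t.label: t.coefficient for t in cfg.coefficients.parts["main"]}
        spec = ModelSpec(
            tuple(Term(t.kind, t.variables) for t in cfg.coefficients.parts["main"]),
            family="tobit",
        )
        fit = fit_tobit(data, spec)
        got = coef_dict(fit)
        for label, tv in truth.items():
            assert abs(got[label] - tv) < 3 * fit.standard_errors[label], label
        assert abs(fit.sigma - cfg.noise_sd) < 3 * fit.standard_errors["sigma"]
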