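"""Design preparation, Gamma/log-link GLM fitting, the model suite,
interaction curves and residual diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from pvskit.stats import (
    ModelSpec,
    fit_gamma_glm,
    fitted_interaction_curves,
    prepare_design,
    residual_diagnostics,
    run_model_suite,
)
from pvskit.synthetic import CohortSpec, simulate_cohort

from _oracles import fit_gamma_direct


@pytest.fixture(scope="module")
def interaction_fit(cohort_465):
    spec = ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction",
                     biomarker="tnf_a", standardize=True)
    X, y = prepare_design(cohort_465, spec)
    return spec, X, y, fit_gamma_glm(X, y)


class TestPrepareDesign:
    def test_continuous_predictors_median_centered(self, cohort_465):
        spec = ModelSpec(form="main", biomarker="cortisol")
        X, _ = prepare_design(cohort_465, spec)
        assert np.median(X["cortisol"]) == pytest.approx(0.0, abs=1e-12)
        assert np.median(X["age"]) == pytest.approx(0.0, abs=1e-12)

    def test_bmi_z_scaled_to_unit_moments(self, cohort_465):
        X, _ = prepare_design(cohort_465, ModelSpec())
        assert X["bmi_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["bmi_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_interaction_is_product_of_centered_terms(self, interaction_fit):
        _, X, _, _ = interaction_fit
        np.testing.assert_allclose(
            X["cortisol:tnf_a"], X["cortisol"] * X["tnf_a"], atol=1e-12)

    def test_listwise_deletion_of_missing(self, cohort_465):
        df = cohort_465.copy()
        df.loc[df.index[:7], "crp"] = np.nan
        X, y = prepare_design(df, ModelSpec(form="main", biomarker="crp"))
        assert len(y) == len(cohort_465) - 7

    def test_zero_variance_column_named_in_error(self, cohort_465):
        df = cohort_465.copy()
        df["trail"] = 3.3
        with pytest.raises(ValueError, match="trail"):
            prepare_design(df, ModelSpec(form="main", biomarker="trail"))

    def test_subgroup_restriction(self, cohort_465):
        spec = ModelSpec(form="main", biomarker="crp", subgroup="AD")
        X, y = prepare_design(cohort_465, spec)
        assert len(y) == (cohort_465["diagnosis"] == "AD").sum()


class TestGammaGLM:
    def test_intercept_only_equals_log_mean(self, cohort_465):
        y = cohort_465["pvsvf_cso"]
        X = pd.DataFrame({"intercept": np.ones(len(y))})
        fit = fit_gamma_glm(X, y)
        assert fit.b[0] == pytest.approx(math.log(y.mean()), abs=1e-8)

    def test_constant_response_zero_dispersion(self):
        y = np.full(30, 0.02)
        X = pd.DataFrame({"intercept": np.ones(30)})
        fit = fit_gamma_glm(X, y)
        assert fit.b[0] == pytest.approx(math.log(0.02), abs=1e-10)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-20)

    def test_known_coefficients_recovered_and_match_direct_mle(self):
        """Simulation at n=5000 with known coefficients and shape 10:
        estimates within 3 SE of truth and equal to direct numerical
        likelihood maximization."""
        rng = np.random.default_rng(42)
        n = 5000
        truth = np.array([-3.9, 0.05, 0.2, -0.07])
        X = pd.DataFrame({
            "intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        })
        mu = np.exp(X.to_numpy() @ truth)
        y = rng.gamma(10.0, mu / 10.0)
        fit = fit_gamma_glm(X, y)
        assert fit.converged
        np.testing.assert_array_less(np.abs(fit.b - truth), 3 * fit.se)
        direct = fit_gamma_direct(X, y)
        np.testing.assert_allclose(fit.b, direct, atol=1e-6)

    def test_matches_statsmodels_reference(self, interaction_fit):
        import statsmodels.api as sm

        _, X, y, fit = interaction_fit
        ref = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        np.testing.assert_allclose(fit.b, ref.params.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse.to_numpy(), rtol=1e-6)

    def test_centering_invariance_of_predictions(self, cohort_465):
        """Centering predictors reparameterizes coefficients but leaves
        fitted means untouched."""
        y = cohort_465["pvsvf_cso"]
        raw = cohort_465["cortisol"].to_numpy()
        for shift in (0.0, raw.mean()):
            Xs = pd.DataFrame({"intercept": np.ones(len(y)), "x": raw - shift})
            fit = fit_gamma_glm(Xs, y)
            mu = np.exp(Xs.to_numpy() @ fit.b)
            if shift == 0.0:
                mu_ref = mu
        np.testing.assert_allclose(mu, mu_ref, rtol=1e-6)

    def test_monotone_reporting(self, interaction_fit):
        _, _, _, fit = interaction_fit
        assert np.all((fit.exp_b > 1) == (fit.b > 0))

    def test_nonpositive_response_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(5)})
        with pytest.raises(ValueError):
            fit_gamma_glm(X, np.array([1.0, 2.0, 0.0, 1.0, 1.0]))

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10), "dup": np.ones(10)})
        with pytest.raises(ValueError):
            fit_gamma_glm(X, np.full(10, 0.5))


class TestModelSuite:
    def test_rows_per_model_equal_coefficient_count(self, cohort_465):
        specs = [
            ModelSpec(outcome="pvsvf_cso", form="main", biomarker="crp"),
            ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction", biomarker="tnf_a"),
            ModelSpec(outcome="pvsvf_bg", form="ace_interaction", biomarker="tnfr2"),
        ]
        table = run_model_suite(cohort_465, specs)
        counts = table.groupby("model").size()
        assert counts[specs[0].label()] == 6   # intercept + marker + 4 covariates
        assert counts[specs[1].label()] == 8   # + exposure + interaction
        assert counts[specs[2].label()] == 8

    def test_outlier_filter_shrinks_analysis_sample(self, cohort_465):
        specs = [ModelSpec(form="main", biomarker="crp")]
        filtered = run_model_suite(cohort_465, specs, outlier_k=1.5)
        unfiltered = run_model_suite(cohort_465, specs, outlier_k=None)
        assert filtered["n"].iloc[0] < unfiltered["n"].iloc[0]

    def test_true_interaction_detected_with_high_power(self):
        """At a sample size calibrated for high power, the generating
        negative cortisol x TNF-a interaction is declared significant in
        at least 80% of replicates."""
        hits = 0
        reps = 60
        for rep in range(reps):
            df = simulate_cohort(CohortSpec(n_subjects=1100, seed=3000 + rep))
            spec = ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction",
                             biomarker="tnf_a", standardize=True)
            X, y = prepare_design(df, spec)
            fit = fit_gamma_glm(X, y)
            hits += fit.pvalues[fit.names.index("cortisol:tnf_a")] < 0.05
        assert hits / reps >= 0.8

    def test_null_apoe4_covariate_leaves_interaction_unchanged(self):
        """Adding an APOE4 indicator with no generating effect moves the
        interaction estimate by far less than its standard error."""
        diffs, ses = [], []
        for rep in range(10):
            df = simulate_cohort(CohortSpec(seed=4000 + rep))
            base = ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction",
                             biomarker="tnf_a", standardize=True)
            sens = ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction",
                             biomarker="tnf_a", standardize=True,
                             extra_covariates=["apoe4"])
            X1, y1 = prepare_design(df, base)
            X2, y2 = prepare_design(df, sens)
            f1, f2 = fit_gamma_glm(X1, y1), fit_gamma_glm(X2, y2)
            diffs.append(f2.coef("cortisol:tnf_a") - f1.coef("cortisol:tnf_a"))
            ses.append(f1.se[f1.names.index("cortisol:tnf_a")])
        assert np.max(np.abs(diffs)) < 0.3 * np.mean(ses)

    def test_small_subgroup_skipped(self, cohort_465):
        tiny = cohort_465.head(30).copy()
        tiny["diagnosis"] = "MCI"
        tiny.loc[tiny.index[:4], "diagnosis"] = "CN"
        specs = [ModelSpec(form="main", biomarker="crp", subgroup="CN")]
        table = run_model_suite(tiny, specs, outlier_k=None)
        assert table.empty


class TestInteractionCurves:
    def test_reference_subject_mean_is_exp_b0(self, interaction_fit):
        spec, _, _, fit = interaction_fit
        curves = fitted_interaction_curves(fit, spec, {"median": 0.0},
                                           np.array([0.0]))
        assert curves["median"]["mu"].iloc[0] == pytest.approx(
            math.exp(fit.coef("intercept")), rel=1e-12)

    def test_zero_interaction_gives_proportional_curves(self, interaction_fit):
        """With b_interaction = 0 the min/max-moderator curves differ by
        a constant log-ratio b_moderator * (max - min)."""
        spec, _, _, fit = interaction_fit
        import dataclasses as dc
        b = fit.b.copy()
        b[fit.names.index("cortisol:tnf_a")] = 0.0
        fit0 = dc.replace(fit, b=b)
        grid = np.linspace(-2, 2, 9)
        lo, hi = -1.3, 2.1
        curves = fitted_interaction_curves(fit0, spec, {"min": lo, "max": hi}, grid)
        log_ratio = np.log(curves["max"]["mu"].to_numpy()
                           / curves["min"]["mu"].to_numpy())
        expected = fit.coef("tnf_a") * (hi - lo)
        np.testing.assert_allclose(log_ratio, expected, atol=1e-10)

    def test_band_brackets_estimate_and_collapses_without_variance(self, interaction_fit):
        spec, _, _, fit = interaction_fit
        grid = np.linspace(-2, 2, 7)
        curves = fitted_interaction_curves(fit, spec, {"max": 1.5}, grid)
        c = curves["max"]
        assert np.all(c["lo"] <= c["mu"]) and np.all(c["mu"] <= c["hi"])
        import dataclasses as dc
        fit0 = dc.replace(fit, cov=np.zeros_like(fit.cov))
        c0 = fitted_interaction_curves(fit0, spec, {"max": 1.5}, grid)["max"]
        np.testing.assert_allclose(c0["lo"], c0["mu"], rtol=1e-12)
        np.testing.assert_allclose(c0["hi"], c0["mu"], rtol=1e-12)

    def test_main_effect_model_rejected(self, cohort_465):
        spec = ModelSpec(form="main", biomarker="crp")
        X, y = prepare_design(cohort_465, spec)
        fit = fit_gamma_glm(X, y)
        with pytest.raises(ValueError):
            fitted_interaction_curves(fit, spec, {"max": 1.0}, np.array([0.0]))


class TestResidualDiagnostics:
    def test_perfect_constant_fit_zero_residuals(self):
        y = np.full(20, 0.03)
        X = pd.DataFrame({"intercept": np.ones(20)})
        d = residual_diagnostics(fit_gamma_glm(X, y))
        np.testing.assert_allclose(d["deviance_residuals"], 0.0, atol=1e-8)

    def test_well_specified_model_near_normal_residuals(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.normal(size=n)
        mu = np.exp(-3.9 + 0.1 * x)
        y = rng.gamma(10.0, mu / 10.0)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        d = residual_diagnostics(fit_gamma_glm(X, y))
        assert abs(d["skewness"]) < 0.2

    def test_misspecified_heavy_tail_increases_skew(self):
        rng = np.random.default_rng(4)
        n = 5000
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y_good = rng.gamma(10.0, np.exp(-3.9) / 10.0 * np.ones(n))
        y_bad = np.exp(rng.normal(math.log(0.02), 1.2, size=n))
        skew_good = abs(residual_diagnostics(fit_gamma_glm(X, y_good))["skewness"])
        skew_bad = abs(residual_diagnostics(fit_gamma_glm(X, y_bad))["skewness"])
        assert skew_bad > skew_good

    def test_qq_table_shapes(self, interaction_fit):
        _, _, _, fit = interaction_fit
        d = residual_diagnostics(fit)
        assert len(d["qq"]) == fit.n
        assert {"theoretical", "sample", "standardized_sample"} <= set(d["qq"].columns)
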