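"""Poisson mixed-model fitting, selection, R2 and prediction."""

from __future__ import annotations

import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

import divebuzz as db
from divebuzz.model import (
    GLMMConvergenceError,
    ModelSpec,
    backward_select,
    fit_glmm,
    predict_counts,
    r_squared,
    standardize,
)

from _oracles import irls_poisson

SPEC3 = ModelSpec(
    predictors=("average_depth", "variance_depth", "variance_vertical_velocity")
)


def poisson_table(rng, n_groups=5, n_per=80, beta=(0.3, 0.6, -0.4), sigma=0.4):
    """Counts from the exact model the fitter assumes."""
    rows = []
    alphas = rng.normal(0, sigma, n_groups)
    for g in range(n_groups):
        x1 = rng.normal(size=n_per)
        x2 = rng.normal(size=n_per)
        lam = np.exp(beta[0] + beta[1] * x1 + beta[2] * x2 + alphas[g])
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": f"g{g}",
                    "buzz_count": rng.poisson(lam),
                    "x1": x1,
                    "x2": x2,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestStandardize:
    def test_mean_zero_sd_one(self, small_metric_table):
        z, record = standardize(small_metric_table, ["average_depth", "sinuosity"])
        assert abs(z["average_depth"].mean()) < 1e-12
        assert abs(z["average_depth"].std(ddof=0) - 1.0) < 1e-12
        assert set(record.means) == {"average_depth", "sinuosity"}

    def test_constant_column_excluded(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero SD"):
            z, record = standardize(t, ["a", "b"])
        assert "a" not in record.means

    def test_test_set_uses_train_statistics(self):
        train = pd.DataFrame({"x": np.arange(10.0)})
        test = pd.DataFrame({"x": np.arange(10.0) + 100.0})
        _, record = standardize(train, ["x"])
        z = record.apply(test, ("x",))
        assert z.mean() > 10  # the shift survives: no per-test re-centering


class TestFitGLMM:
    def test_intercept_only_equals_log_mean_count(self, quiet_fit):
        t = pd.DataFrame(
            {"individual_id": ["a"] * 20 + ["b"] * 20, "buzz_count": 3, "x": 0.0}
        )
        t["x"] = np.random.default_rng(0).normal(size=40)
        fit = fit_glmm(ModelSpec(predictors=("x",)), t)
        assert fit.intercept == pytest.approx(np.log(3), abs=1e-4)

    def test_single_group_matches_irls_oracle(self, quiet_fit):
        rng = np.random.default_rng(1)
        t = poisson_table(rng, n_groups=1, n_per=400, sigma=0.0)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        _, record = standardize(t, ["x1", "x2"])
        X = np.column_stack([np.ones(len(t)), record.apply(t, ("x1", "x2"))])
        beta_ref, ll_ref = irls_poisson(t["buzz_count"].to_numpy(), X)
        est = fit.coefficients["estimate"].to_numpy()
        assert np.allclose(est, beta_ref, rtol=1e-3)
        assert fit.random_intercept_variance == 0.0
        assert fit.log_likelihood == pytest.approx(ll_ref, rel=1e-6)

    def test_zero_variance_truth_matches_plain_poisson(self, quiet_fit):
        rng = np.random.default_rng(2)
        t = poisson_table(rng, n_groups=6, n_per=300, sigma=0.0)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        _, record = standardize(t, ["x1", "x2"])
        X = np.column_stack([np.ones(len(t)), record.apply(t, ("x1", "x2"))])
        beta_ref, _ = irls_poisson(t["buzz_count"].to_numpy(), X)
        assert np.allclose(
            fit.coefficients["estimate"].to_numpy(), beta_ref, rtol=1e-3, atol=1e-4
        )
        assert fit.random_intercept_variance < 0.02

    def test_aic_identity(self, quiet_fit):
        rng = np.random.default_rng(3)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), poisson_table(rng))
        n_params = 3 + 1  # intercept + 2 slopes + variance
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * n_params)

    def test_adding_constant_shifts_only_intercept(self, quiet_fit):
        rng = np.random.default_rng(4)
        t = poisson_table(rng)
        fit1 = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        t2 = t.copy()
        t2["x1"] = t2["x1"] + 57.0
        fit2 = fit_glmm(ModelSpec(predictors=("x1", "x2")), t2)
        assert np.allclose(
            fit1.coefficients["estimate"], fit2.coefficients["estimate"], atol=1e-4
        )

    def test_noninteger_response_rejected(self):
        t = pd.DataFrame({"individual_id": ["a"] * 3, "buzz_count": [0.5, 1, 2], "x": 1.0})
        with pytest.raises(ValueError, match="counts"):
            fit_glmm(ModelSpec(predictors=("x",)), t)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_lme4_glmer(self, tmp_path, quiet_fit):
        """Independent cross-check against lme4's adaptive-quadrature fit."""
        rng = np.random.default_rng(5)
        t = poisson_table(rng, n_groups=6, n_per=60, sigma=0.5)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        z, record = standardize(t, ["x1", "x2"])
        z[["individual_id", "buzz_count", "x1", "x2"]].to_csv(
            tmp_path / "d.csv", index=False
        )
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{tmp_path / "d.csv"}")\n'
            "m <- glmer(buzz_count ~ x1 + x2 + (1|individual_id), data=d,"
            " family=poisson, nAGQ=15)\n"
            'cat(fixef(m), unlist(VarCorr(m))[1], sqrt(diag(vcov(m))), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.split()]
        coef_r, sigma2_r, se_r = vals[:3], vals[3], vals[4:7]
        assert np.allclose(fit.coefficients["estimate"], coef_r, atol=5e-4)
        assert fit.random_intercept_variance == pytest.approx(sigma2_r, abs=5e-3)
        assert np.allclose(fit.coefficients["std_error"], se_r, rtol=5e-3)


class TestBackwardSelect:
    def test_single_predictor_unchanged(self, quiet_fit):
        rng = np.random.default_rng(6)
        t = poisson_table(rng)
        best, trace = backward_select(ModelSpec(predictors=("x1",)), t)
        assert best.spec.predictors == ("x1",)
        assert len(trace) == 1

    def test_noise_predictor_eliminated(self, small_metric_table, quiet_fit):
        t = small_metric_table.copy()
        t["pure_noise"] = np.random.default_rng(7).normal(size=len(t))
        best, trace = backward_select(
            ModelSpec(predictors=SPEC3.predictors + ("pure_noise",)), t
        )
        assert "pure_noise" not in best.spec.predictors
        assert (trace["removed"] == "pure_noise").any()

    def test_convergence_error_names_submodel(self, quiet_fit):
        # a predictor that perfectly separates counts can break sub-fits;
        # here we just check errors propagate with context when raised
        rng = np.random.default_rng(8)
        t = poisson_table(rng)
        best, _ = backward_select(ModelSpec(predictors=("x1", "x2")), t)
        assert best.converged


class TestRSquaredAndPrediction:
    def test_r2_equal_when_no_random_variance(self, quiet_fit):
        rng = np.random.default_rng(9)
        t = poisson_table(rng, sigma=0.0, n_groups=6, n_per=200)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        if fit.random_intercept_variance == 0.0:
            assert fit.r2_marginal == pytest.approx(fit.r2_conditional)
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0

    def test_intercept_only_marginal_zero(self, quiet_fit):
        rng = np.random.default_rng(10)
        t = poisson_table(rng, beta=(0.5, 0.0, 0.0))
        t["const_like"] = rng.normal(size=len(t)) * 1e-12 + 1.0
        fit = fit_glmm(ModelSpec(predictors=("x1",)), t)
        fit.coefficients.loc["x1", "estimate"] = 0.0
        r2m, r2c = r_squared(fit, t)
        assert r2m == 0.0
        assert r2c >= 0.0

    def test_trigamma_variant_close_to_lognormal_at_high_rate(self, quiet_fit):
        rng = np.random.default_rng(11)
        t = poisson_table(rng, beta=(2.0, 0.5, -0.3))
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        lg = r_squared(fit, t, variant="lognormal")
        tg = r_squared(fit, t, variant="trigamma")
        assert lg[0] == pytest.approx(tg[0], rel=0.1)

    def test_prediction_at_training_mean(self, quiet_fit):
        rng = np.random.default_rng(12)
        t = poisson_table(rng)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        mean_row = pd.DataFrame(
            {"x1": [t["x1"].mean()], "x2": [t["x2"].mean()]}
        )
        lam, counts = predict_counts(fit, mean_row)
        assert lam[0] == pytest.approx(np.exp(fit.intercept))

    def test_link_monotonicity(self, quiet_fit):
        rng = np.random.default_rng(13)
        t = poisson_table(rng, beta=(0.2, 0.8, -0.4))
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), t)
        lo = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        hi = pd.DataFrame({"x1": [2.0], "x2": [0.0]})
        assert predict_counts(fit, hi)[0][0] > predict_counts(fit, lo)[0][0]

    def test_missing_predictor_raises(self, quiet_fit):
        rng = np.random.default_rng(14)
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), poisson_table(rng))
        with pytest.raises(KeyError):
            predict_counts(fit, pd.DataFrame({"x1": [0.0]}))

    def test_heldout_calibration(self, quiet_fit):
        """Population-level predictions for unseen individuals track the
        observed mean count within sampling error."""
        rng = np.random.default_rng(15)
        t = poisson_table(rng, n_groups=8, n_per=150, sigma=0.2)
        train = t[t["individual_id"] < "g6"]
        test = t[t["individual_id"] >= "g6"]
        fit = fit_glmm(ModelSpec(predictors=("x1", "x2")), train)
        lam, _ = predict_counts(fit, test)
        obs = test["buzz_count"].to_numpy()
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(lam.mean() - obs.mean()) < 3 * se + 0.25 * obs.mean()
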