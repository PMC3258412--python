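import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from conftest import random_features
from ohnolog.model import (
    GrandMeanImputer,
    RetentionLogit,
    SDScaler,
    build_design,
    fit_logistic,
    impute_grand_mean,
    sensitivity_complete_case,
    standardize,
)


def direct_ml_oracle(X, y):
    """Independent oracle: maximize the Bernoulli likelihood numerically
    (BFGS on the negative log-likelihood), no IRLS involved."""
    Xd = np.column_stack([np.ones(len(X)), X])

    def nll(beta):
        eta = Xd @ beta
        return -(y @ eta - np.logaddexp(0, eta).sum())

    def grad(beta):
        mu = 1 / (1 + np.exp(-(Xd @ beta)))
        return -Xd.T @ (y - mu)

    res = optimize.minimize(nll, np.zeros(Xd.shape[1]), jac=grad,
                            method="BFGS", options={"gtol": 1e-10})
    return res.x


class TestSDScaler:
    def test_divides_by_observed_sd_preserving_missing(self):
        X = pd.DataFrame({"a": [2.0, 4.0, np.nan]})
        out = SDScaler().fit_transform(X)
        sd = np.std([2.0, 4.0], ddof=1)
        np.testing.assert_allclose(out["a"][:2], [2 / sd, 4 / sd])
        assert np.isnan(out["a"][2])

    def test_idempotent_on_unit_sd_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = x / x.std(ddof=1)
        X = pd.DataFrame({"a": x})
        out = SDScaler().fit_transform(X)
        np.testing.assert_allclose(out["a"], x, atol=1e-12)

    def test_no_centering(self):
        X = pd.DataFrame({"a": [10.0, 12.0, 14.0]})
        out = SDScaler().fit_transform(X)
        assert (out["a"] > 0).all()

    def test_zero_variance_rejected_by_name(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            SDScaler().fit(X)

    def test_recovers_generator_sds(self, default_dataset):
        f = default_dataset.features
        scaled, sds = standardize(f)
        obs = f["dN"].dropna()
        assert sds["dN"] == pytest.approx(obs.std(ddof=1))
        # scaled observed values have unit SD
        assert scaled["dN"].dropna().std(ddof=1) == pytest.approx(1.0)


class TestGrandMeanImputer:
    def test_mean_substitution(self):
        X = pd.DataFrame({"a": [1.0, 3.0, np.nan]})
        out = GrandMeanImputer().fit_transform(X)
        assert out["a"].tolist() == [1.0, 3.0, 2.0]

    def test_identity_without_missingness(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(GrandMeanImputer().fit_transform(X), X)

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError, match="all values missing"):
            GrandMeanImputer().fit(pd.DataFrame({"a": [np.nan, np.nan]}))

    def test_post_imputation_sd_shrinks_and_is_not_rescaled(self):
        """With fraction f of cells imputed at the mean, the column SD drops
        to ~sqrt(1-f) of the observed SD — and must stay there."""
        rng = np.random.default_rng(1)
        n = 20000
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        xm = x.copy()
        xm[rng.random(n) < 0.5] = np.nan
        df, _ = random_features(n=n, p=1, seed=2)
        df["v0"] = xm
        design = build_design(df)
        post_sd = design.X[:, 0].std(ddof=1)
        f = design.imputed_mask[:, 0].mean()
        assert post_sd == pytest.approx(np.sqrt(1 - f), rel=0.05)
        assert post_sd < 0.9  # clearly below 1: no re-normalization happened

    def test_imputed_mask_marks_exactly_the_missing_cells(self):
        df, _ = random_features(n=100, p=3, seed=3, missing_rate=0.3)
        design = build_design(df)
        np.testing.assert_array_equal(
            design.imputed_mask, df[["v0", "v1", "v2"]].isna().to_numpy()
        )
        assert not np.isnan(design.X).any()


class TestFitLogistic:
    def test_two_by_two_table_closed_form(self):
        """Single 0/1 covariate: the slope is the log odds ratio ln(ad/bc)."""
        a, b, c, d = 40, 10, 10, 40  # (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0)
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        from ohnolog._glm import fit_logit
        res = fit_logit(np.column_stack([np.ones_like(x), x]), y)
        assert res.converged
        assert res.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_ml_oracle(self, seed):
        df, _ = random_features(n=500, p=10, seed=seed)
        design = build_design(df)
        fit = fit_logistic(design)
        assert fit.converged
        expected = direct_ml_oracle(design.X, design.y)
        np.testing.assert_allclose(
            np.concatenate([[fit.intercept], fit.coefficients]),
            expected, atol=1e-6,
        )

    def test_matches_statsmodels_coefficients_and_ses(self):
        sm = pytest.importorskip("statsmodels.api")
        df, _ = random_features(n=800, p=5, seed=99)
        design = build_design(df)
        fit = fit_logistic(design)
        ref = sm.Logit(design.y, sm.add_constant(design.X)).fit(disp=0)
        np.testing.assert_allclose(fit.intercept, ref.params[0], atol=1e-7)
        np.testing.assert_allclose(fit.coefficients, ref.params[1:], atol=1e-7)
        np.testing.assert_allclose(fit.standard_errors, ref.bse[1:], rtol=1e-5)
        np.testing.assert_allclose(fit.log_likelihood, ref.llf, atol=1e-6)

    def test_reordering_rows_and_variables_is_irrelevant(self):
        df, _ = random_features(n=300, p=4, seed=5, missing_rate=0.1)
        fit1 = fit_logistic(build_design(df))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm][["outcome", "v2", "v0", "v3", "v1"]]
        fit2 = fit_logistic(build_design(df2))
        for name in ["v0", "v1", "v2", "v3"]:
            i, j = fit1.variable_names.index(name), fit2.variable_names.index(name)
            assert fit1.coefficients[i] == pytest.approx(fit2.coefficients[j])

    def test_raw_covariate_scale_is_absorbed(self):
        df, _ = random_features(n=400, p=3, seed=6)
        fit1 = fit_logistic(build_design(df))
        df2 = df.copy()
        df2["v1"] = df2["v1"] * 1234.5
        fit2 = fit_logistic(build_design(df2))
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, rtol=1e-6)

    def test_centering_does_not_change_slopes(self):
        df, _ = random_features(n=400, p=3, seed=7)
        fit1 = fit_logistic(build_design(df))
        df2 = df.copy()
        for v in ["v0", "v1", "v2"]:
            df2[v] = df2[v] - df2[v].mean() + 3.0
        fit2 = fit_logistic(build_design(df2))
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-6)

    def test_null_model_wald_calibration(self):
        """Outcome independent of X: ~95% of 95% intervals cover zero."""
        rng = np.random.default_rng(8)
        cover = 0
        total = 0
        for _ in range(100):
            n = 400
            X = rng.normal(size=(n, 2))
            y = rng.binomial(1, 0.5, size=n)
            df = pd.DataFrame(X, columns=["v0", "v1"])
            df.insert(0, "outcome", y)
            fit = fit_logistic(build_design(df))
            cover += int(np.all(np.abs(fit.coefficients) < 1.96 * fit.standard_errors))
            total += 1
        # joint coverage of 2 near-independent intervals ~ 0.95^2 = 0.90
        assert 0.80 <= cover / total <= 0.98

    def test_complete_separation_flagged_not_raised(self):
        x = np.linspace(-1, 1, 50)
        df = pd.DataFrame({"outcome": (x > 0).astype(int), "v0": x})
        fit = fit_logistic(build_design(df))
        assert not fit.converged
        assert "separation" in fit.message or "convergence" in fit.message


class TestCompleteCase:
    def test_equals_full_fit_without_missingness(self):
        df, _ = random_features(n=300, p=3, seed=9)
        full = fit_logistic(build_design(df))
        cc = sensitivity_complete_case(df)
        np.testing.assert_allclose(full.coefficients, cc.coefficients, atol=1e-8)

    def test_row_count_is_number_of_fully_observed_rows(self):
        df, _ = random_features(n=300, p=3, seed=10, missing_rate=0.2)
        cc = sensitivity_complete_case(df)
        assert cc.n_obs == int((~df[["v0", "v1", "v2"]].isna().any(axis=1)).sum())

    def test_mcar_complete_case_recovery(self):
        """MCAR missingness: complete-case estimates stay consistent."""
        beta = np.array([0.8, -0.5, 0.3])
        df, _ = random_features(n=6000, p=3, seed=11, missing_rate=0.2, beta=beta)
        cc = sensitivity_complete_case(df)
        sds = df[["v0", "v1", "v2"]].std(ddof=1)  # ~1: beta is per-SD truth
        for j in range(3):
            assert abs(cc.coefficients[j] - beta[j] * sds.iloc[j]) < 2 * cc.standard_errors[j]

    def test_few_complete_cases_warns(self):
        df, _ = random_features(n=60, p=5, seed=12, missing_rate=0.15)
        with pytest.warns(UserWarning, match="complete cases"):
            sensitivity_complete_case(df)


class TestRetentionLogitEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        est = RetentionLogit(max_iter=50)
        assert clone(est).get_params()["max_iter"] == 50
        df, _ = random_features(n=200, p=3, seed=13)
        X, y = df[["v0", "v1", "v2"]], df["outcome"]
        est.fit(X, y)
        assert est.coef_.shape == (3,)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}

    def test_predict_handles_missing_via_training_imputation(self):
        df, _ = random_features(n=200, p=2, seed=14, missing_rate=0.1)
        est = RetentionLogit().fit(df[["v0", "v1"]], df["outcome"])
        new = pd.DataFrame({"v0": [np.nan], "v1": [0.0]})
        assert np.isfinite(est.predict_proba(new)).all()

    def test_functional_wrapper_agreement(self):
        df, _ = random_features(n=300, p=3, seed=15, missing_rate=0.1)
        est = RetentionLogit().fit(df[["v0", "v1", "v2"]], df["outcome"])
        fn = fit_logistic(build_design(df))
        np.testing.assert_allclose(est.coef_, fn.coefficients, atol=1e-8)
        np.testing.assert_allclose(est.bse_, fn.standard_errors, atol=1e-8)
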