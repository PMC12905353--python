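import dataclasses

import numpy as np
import pytest
from scipy.special import expit, logit

import fireglm as fg
from fireglm.glm import (
    RankDeficiencyError,
    fit_glm,
    partial_residuals,
    predict,
    predictive_interval,
)
from fireglm.predictors import PREDICTORS


def toy_design(n: int, seed: int = 0) -> np.ndarray:
    """Random full-rank 16-column design for closed-form toys."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, len(PREDICTORS)))


def irls_logit(X: np.ndarray, y: np.ndarray, iters: int = 50) -> np.ndarray:
    """Independent Newton/IRLS oracle for the logit mean model."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    for _ in range(iters):
        mu = expit(A @ beta)
        W = mu * (1 - mu)
        step = np.linalg.solve(A.T @ (W[:, None] * A), A.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestFitGlm:
    def test_intercept_only_saturated_mean(self):
        X = toy_design(400)
        y = np.full(400, 0.2)
        model = fit_glm(X, y, "BA")
        assert expit(model.beta[0]) == pytest.approx(0.2, abs=1e-10)
        np.testing.assert_allclose(model.beta[1:], 0.0, atol=1e-8)

    def test_binary_predictor_recovers_log_odds_ratio(self):
        # group means 0.2 / 0.6: raw slope = log((0.6/0.4)/(0.2/0.8)) = log 6
        n = 400
        X = toy_design(n, seed=1)
        b = np.repeat([0.0, 1.0], n // 2)
        X[:, 0] = b
        y = np.where(b == 1, 0.6, 0.2)
        model = fit_glm(X, y, "BA")
        raw_slope = model.beta[1] / model.x_std[0]
        assert raw_slope == pytest.approx(np.log(6.0), abs=1e-6)

    def test_agrees_with_independent_irls_oracle(self, dataset):
        Xmat = dataset.predictors.matrix()
        y = dataset.fire.BA.ravel()
        model = fit_glm(dataset.predictors, y, "BA")
        Z = (Xmat - model.x_mean) / model.x_std
        expected = irls_logit(Z, y)
        np.testing.assert_allclose(model.beta, expected, atol=1e-6)

    def test_quasi_point_estimates_match_plain_family_se_scaled(self, dataset):
        import statsmodels.api as sm

        y = dataset.fire.BA.ravel()
        model = fit_glm(dataset.predictors, y, "BA")
        Z = (dataset.predictors.matrix() - model.x_mean) / model.x_std
        A = np.column_stack([np.ones(len(y)), Z])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = sm.GLM(y, A, family=sm.families.Binomial()).fit(scale=1.0)
        np.testing.assert_allclose(model.beta, plain.params, atol=1e-8)
        ratio = model.se / plain.bse
        np.testing.assert_allclose(ratio, np.sqrt(model.dispersion), rtol=1e-8)

    def test_permuting_cells_leaves_fit_unchanged(self, dataset):
        y = dataset.fire.BA.ravel()
        Xmat = dataset.predictors.matrix()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        a = fit_glm(Xmat, y, "BA")
        b = fit_glm(Xmat[perm], y[perm], "BA")
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)
        np.testing.assert_allclose(a.dispersion, b.dispersion, rtol=1e-10)

    def test_collinear_design_rejected_with_names(self, dataset):
        Xmat = dataset.predictors.matrix().copy()
        Xmat[:, PREDICTORS.index("crop")] = 2.0 * Xmat[:, PREDICTORS.index("roads")]
        with pytest.raises(RankDeficiencyError, match="collinear|constant"):
            fit_glm(Xmat, dataset.fire.BA.ravel(), "BA")

    def test_too_few_cells_rejected(self):
        X = toy_design(100)
        with pytest.raises(ValueError, match="cells"):
            fit_glm(X, np.full(100, 0.2), "BA")

    def test_fs_normalisation_constants_stored(self, dataset, models):
        fs = dataset.fire.FS.ravel()
        trained = dataset.fire.BA.ravel() > 0  # observed-fire cells
        model = models["FS"]
        assert model.norm_min == pytest.approx(fs[trained].min())
        assert model.norm_max == pytest.approx(fs[trained].max())
        assert model.family == "quasi-Poisson" and model.link == "log"

    def test_slope_recovery_on_synthetic_truth(self):
        ds = fg.generate_dataset(seed=42, nlon=100, nlat=50, zero_fraction=0.0)
        model = fit_glm(ds.predictors, ds.fire.BA.ravel(), "BA")
        rel = np.abs(model.beta[1:] - ds.truth.beta_BA[1:]) / np.abs(ds.truth.beta_BA[1:])
        assert np.median(rel) < 0.05


class TestPredict:
    def test_training_design_returns_fitted_values(self, dataset, models):
        mu = predict(models["BA"], dataset.predictors).ravel()
        Z = models["BA"]._train_Z
        manual = expit(models["BA"].beta[0] + Z @ models["BA"].beta[1:])
        np.testing.assert_allclose(mu, manual, rtol=1e-12)
        assert mu.min() > 0 and mu.max() < 1

    def test_mean_predictors_give_inverse_link_of_intercept(self, models):
        model = models["BA"]
        X = model.x_mean[None, :]
        assert predict(model, X)[0] == pytest.approx(expit(model.beta[0]), rel=1e-12)

    def test_monotone_in_positive_coefficient_predictor(self, models):
        model = models["BA"]
        j = int(np.argmax(model.beta[1:]))
        X = np.repeat(model.x_mean[None, :], 2, axis=0)
        X[1, j] += model.x_std[j]
        lo, hi = predict(model, X)
        assert hi > lo

    def test_layout_mismatch_rejected(self, models):
        with pytest.raises(ValueError, match="16 columns"):
            predict(models["BA"], np.zeros((5, 4)))

    def test_denormalised_fs_predictions_in_physical_units(self, dataset, models):
        fs_pred = predict(models["FS"], dataset.predictors, denormalise=True)
        assert fs_pred.min() >= models["FS"].norm_min
        # physical medians, km^2 scale of the observations
        obs = dataset.fire.FS[dataset.fire.FS > 0]
        assert 0.1 * obs.mean() < fs_pred.mean() < 10 * obs.mean()


class TestPredictiveInterval:
    def test_bounds_bracket_fitted_and_stay_in_unit_interval(self, dataset, models):
        lower, upper = predictive_interval(models["BA"], dataset.predictors)
        mu = predict(models["BA"], dataset.predictors)
        assert np.all(lower <= mu + 1e-12) and np.all(mu <= upper + 1e-12)
        assert lower.min() > 0 and upper.max() < 1

    def test_degenerate_zero_covariance_collapses_to_fitted(self, dataset, models):
        model = dataclasses.replace(
            models["BA"], cov_beta=np.zeros_like(models["BA"].cov_beta))
        lower, upper = predictive_interval(model, dataset.predictors)
        mu = predict(model, dataset.predictors)
        np.testing.assert_allclose(lower, mu, rtol=1e-12)
        np.testing.assert_allclose(upper, mu, rtol=1e-12)

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n, (nlon, nlat) in {"small": (25, 20), "large": (100, 50)}.items():
            ds = fg.generate_dataset(seed=9, nlon=nlon, nlat=nlat, zero_fraction=0.0)
            model = fit_glm(ds.predictors, ds.fire.BA.ravel(), "BA")
            lo, hi = predictive_interval(model, ds.predictors)
            widths[n] = (hi - lo).mean()
        assert widths["large"] < widths["small"]

    def test_invalid_level_rejected(self, models, dataset):
        with pytest.raises(ValueError, match="level"):
            predictive_interval(models["BA"], dataset.predictors, level=1.5)

    def test_literal_multiplicative_variant_available(self, dataset, models):
        lower, upper = predictive_interval(models["BA"], dataset.predictors,
                                           literal=True)
        mu = predict(models["BA"], dataset.predictors)
        assert np.all(lower <= mu) and np.all(mu <= upper)


class TestPartialResiduals:
    def test_noiseless_single_predictor_lies_on_line(self):
        X = toy_design(400, seed=5)
        b0, b1 = -1.0, 0.8
        # response generated from predictor 3 alone, no noise
        y = expit(b0 + b1 * X[:, 3])
        model = fit_glm(X, y, "BA")
        zj, pr = partial_residuals(model, PREDICTORS[3])
        slope = np.polyfit(zj, pr, 1)[0]
        assert slope == pytest.approx(model.beta[4], rel=1e-6)
        assert np.abs(pr - model.beta[4] * zj).max() < 1e-6

    def test_ls_slope_through_partial_residuals_tracks_coefficient(
            self, dataset, models):
        model = models["BA"]
        j = PREDICTORS.index("GPP")
        zj, pr = partial_residuals(model, "GPP")
        slope = np.polyfit(zj, pr, 1)[0]
        assert slope == pytest.approx(model.beta[1 + j], abs=0.15)

    def test_unknown_predictor_rejected(self, models):
        with pytest.raises(ValueError, match="unknown predictor"):
            partial_residuals(models["BA"], "snow")


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, dataset, models, tmp_path):
        path = tmp_path / "model.json"
        models["FS"].save(path)
        loaded = fg.FittedGLM.load(path)
        np.testing.assert_allclose(
            predict(loaded, dataset.predictors, denormalise=True),
            predict(models["FS"], dataset.predictors, denormalise=True))
        assert loaded.norm_max == models["FS"].norm_max
        np.testing.assert_allclose(loaded.cov_beta, models["FS"].cov_beta)
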