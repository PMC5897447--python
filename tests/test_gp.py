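"""Kernel construction and exact GP inference against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serumgp as sg
from serumgp.gp import GPNumericalError

from conftest import full_model_spec, random_design


class TestKernels:
    def test_se_age_zero_distance_gives_variance(self):
        X = pd.DataFrame({"age": [5.0, 5.0]})
        K = sg.build_kernel(sg.KernelSpec("se_age", ("age",), 2.5, 10.0), X)
        np.testing.assert_allclose(K, 2.5 * np.ones((2, 2)))

    def test_categorical_id_blocks(self):
        X = pd.DataFrame({"id": ["A", "A", "B"]})
        K = sg.build_kernel(sg.KernelSpec("categorical", ("id",), 1.5), X)
        expected = 1.5 * np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(K, expected)

    def test_seasonal_period_symmetry(self):
        spec = sg.KernelSpec("periodic_season", ("season",), 1.0, 0.8)
        X = pd.DataFrame({"season": [0.0, 12.0, 3.0]})
        K = sg.build_kernel(spec, X)
        # a 12-month shift is a full period: same covariance as lag 0
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 2] < K[0, 0]

    def test_product_kernel_zero_across_subjects(self):
        spec = sg.KernelSpec("product", ("age", "id"), 1.0, 10.0)
        X = pd.DataFrame({"age": [3.0, 3.0], "id": ["A", "B"]})
        K = sg.build_kernel(spec, X)
        assert K[0, 1] == 0.0
        assert K[0, 0] == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="lengthscale"):
            sg.KernelSpec("se_age", ("age",), 1.0, -1.0)
        with pytest.raises(ValueError, match="variance"):
            sg.KernelSpec("categorical", ("id",), -0.5)
        with pytest.raises(ValueError, match="distinct"):
            sg.KernelSpec("product", ("age",), 1.0, 5.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_symmetry_and_psd(self, trial):
        """Every built kernel matrix is symmetric PSD up to 1e-8."""
        rng = np.random.default_rng(100 + trial)
        X = random_design(rng, 12)
        spec = full_model_spec(rng)
        K = sg.model_covariance(spec, X, include_noise=False)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLogMarginalLikelihood:
    def test_single_point_noise_only_closed_form(self):
        spec = sg.AdditiveModelSpec(components=(), noise_variance=1.0)
        X = pd.DataFrame({"age": [3.0]})
        lml = sg.log_marginal_likelihood(spec, X, np.array([0.0]))
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_dense_multivariate_normal_oracle(self, trial):
        """Exact GP evidence equals the brute-force Gaussian density."""
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(2, 9))
        X = random_design(rng, n)
        spec = full_model_spec(rng)
        y = rng.standard_normal(n)
        K = sg.model_covariance(spec, X)
        oracle = stats.multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=K, allow_singular=True)
        assert sg.log_marginal_likelihood(spec, X, y) == pytest.approx(
            oracle, abs=1e-8)

    def test_noise_increase_decreases_evidence_at_zero_response(self):
        rng = np.random.default_rng(7)
        X = random_design(rng, 6)
        y = np.zeros(6)
        spec1 = full_model_spec(rng)
        spec2 = sg.AdditiveModelSpec(spec1.components,
                                     spec1.noise_variance * 2.0)
        # with y = 0 only the -0.5 log|K| term varies, and it shrinks
        assert sg.log_marginal_likelihood(spec2, X, y) < \
            sg.log_marginal_likelihood(spec1, X, y)


def _fit_simple(y, X, seed=0, n_restarts=3):
    spec = sg.AdditiveModelSpec(components=(
        sg.KernelSpec("se_age", ("age",), 1.0, 12.0),
        sg.KernelSpec("categorical", ("id",), 1.0),
    ))
    return sg.fit_hyperparameters(spec, X, y, n_restarts=n_restarts,
                                  seed=seed)


class TestFitHyperparameters:
    def test_same_seed_identical_fit(self, small_design):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(len(small_design))
        f1 = _fit_simple(y, small_design, seed=42)
        f2 = _fit_simple(y, small_design, seed=42)
        assert f1.log_marginal_likelihood == f2.log_marginal_likelihood
        assert f1.spec == f2.spec

    def test_stored_lml_reproducible_from_spec(self, small_design):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(len(small_design))
        fit = _fit_simple(y, small_design)
        recomputed = sg.log_marginal_likelihood(fit.spec, fit.X, fit.y)
        assert recomputed == pytest.approx(fit.log_marginal_likelihood,
                                           abs=1e-8)

    def test_white_noise_shrinks_signal_variances(self, small_annotation):
        obs, _ = sg.simulate_protein(small_annotation,
                                     sg.EffectConfig(noise=1.0), seed=5)
        X = sg.design_matrix(small_annotation)
        fit = _fit_simple(obs.to_numpy(), X, seed=1)
        for comp in fit.spec.components:
            assert comp.variance < 0.2
        # standardized response: noise variance close to 1
        assert 0.6 < fit.spec.noise_variance < 1.4

    def test_lengthscale_recovery_within_factor_two(self, small_annotation):
        true_ell = 10.0
        obs, _ = sg.simulate_protein(
            small_annotation,
            sg.EffectConfig(age=2.0, noise=0.05, age_lengthscale=true_ell),
            seed=8)
        X = sg.design_matrix(small_annotation)
        spec = sg.AdditiveModelSpec(components=(
            sg.KernelSpec("se_age", ("age",), 1.0, 12.0),))
        fit = sg.fit_hyperparameters(spec, X, obs.to_numpy(), n_restarts=5,
                                     seed=2)
        ell = fit.spec.components[0].lengthscale
        assert true_ell / 2 <= ell <= true_ell * 2

    def test_too_few_observations_rejected(self, small_design):
        y = np.full(len(small_design), np.nan)
        y[:3] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match=">=4"):
            _fit_simple(y, small_design)


class TestPredict:
    def test_two_point_hand_solve(self):
        """n = 2 posterior mean equals the explicit 2x2 linear algebra."""
        X = pd.DataFrame({"age": [3.0, 6.0], "id": ["A", "A"]})
        spec = sg.AdditiveModelSpec(
            components=(sg.KernelSpec("se_age", ("age",), 1.0, 5.0),),
            noise_variance=0.5)
        y = np.array([1.0, -1.0])
        fit = sg.GPFit.__new__(sg.GPFit)  # build the fit by hand
        import scipy.linalg as sla
        K = sg.model_covariance(spec, X)
        L = sla.cholesky(K, lower=True)
        fit.__init__(spec=spec, X=X, y=y, y_mean=0.0, y_sd=1.0,
                     log_marginal_likelihood=0.0, _L=L,
                     _alpha=sla.cho_solve((L, True), y))
        Xq = pd.DataFrame({"age": [4.0], "id": ["A"]})
        mean, var = sg.predict(fit, Xq)
        k = np.exp(-np.array([1.0, 4.0]) / (2 * 25.0))
        expected = k @ np.linalg.solve(K, y)
        assert mean[0] == pytest.approx(expected, abs=1e-10)
        expected_var = 1.0 - k @ np.linalg.solve(K, k)
        assert var[0] == pytest.approx(expected_var, abs=1e-10)

    def test_interpolation_limit_small_noise(self, small_annotation):
        obs, _ = sg.simulate_protein(
            small_annotation, sg.EffectConfig(age=1.0, noise=1e-4), seed=3)
        X = sg.design_matrix(small_annotation)
        spec = sg.AdditiveModelSpec(components=(
            sg.KernelSpec("se_age", ("age",), 1.0, 12.0),
            sg.KernelSpec("categorical", ("id",), 1.0),))
        fit = sg.fit_hyperparameters(spec, X, obs.to_numpy(), n_restarts=3,
                                     seed=0)
        mean, _ = sg.predict(fit, X)
        np.testing.assert_allclose(mean, obs.to_numpy(), atol=0.05)

    def test_far_extrapolation_reverts_to_prior(self, small_design):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(len(small_design))
        fit = _fit_simple(y, small_design, seed=1)
        Xq = small_design.iloc[[0]].copy()
        Xq["age"] = 10_000.0
        Xq["id"] = "UNSEEN"
        mean, var = sg.predict(fit, Xq)
        total_signal = sum(c.variance for c in fit.spec.components)
        assert mean[0] == pytest.approx(fit.y_mean, abs=1e-6)
        assert var[0] == pytest.approx(fit.y_sd**2 * total_signal, rel=1e-6)


class TestDecompose:
    def test_single_component_equals_total(self, small_design):
        rng = np.random.default_rng(21)
        y = rng.standard_normal(len(small_design))
        spec = sg.AdditiveModelSpec(components=(
            sg.KernelSpec("se_age", ("age",), 1.0, 12.0),))
        fit = sg.fit_hyperparameters(spec, small_design, y, n_restarts=2,
                                     seed=0)
        dec = sg.decompose(fit)
        np.testing.assert_allclose(dec.means["age"] + dec.intercept,
                                   dec.total, atol=1e-10)

    def test_components_sum_to_posterior_mean(self, small_annotation):
        obs, _ = sg.simulate_protein(
            small_annotation,
            sg.EffectConfig(age=1.0, id=0.5, location=0.5, noise=0.5),
            seed=6)
        X = sg.design_matrix(small_annotation)
        spec = sg.CandidateModel(frozenset({"age", "location"})).spec()
        fit = sg.fit_hyperparameters(spec, X, obs.to_numpy(), n_restarts=2,
                                     seed=0)
        dec = sg.decompose(fit)
        total = sum(dec.means.values()) + dec.intercept
        np.testing.assert_allclose(total, dec.total, atol=1e-8)
        mean, _ = sg.predict(fit, X)
        np.testing.assert_allclose(dec.total, mean, atol=1e-8)

    def test_shares_sum_to_one(self, small_annotation):
        obs, _ = sg.simulate_protein(
            small_annotation, sg.EffectConfig(age=1.0, id=1.0, noise=1.0),
            seed=7)
        X = sg.design_matrix(small_annotation)
        spec = sg.CandidateModel(frozenset({"age"})).spec()
        fit = sg.fit_hyperparameters(spec, X, obs.to_numpy(), n_restarts=2,
                                     seed=0)
        dec = sg.decompose(fit)
        total = sum(dec.variance_shares.values()) + dec.noise_share
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_location_offset_dominates_age(self, small_annotation):
        obs, _ = sg.simulate_protein(
            small_annotation, sg.EffectConfig(location=4.0, noise=0.25),
            seed=9)
        X = sg.design_matrix(small_annotation)
        spec = sg.CandidateModel(frozenset({"age", "location"})).spec()
        fit = sg.fit_hyperparameters(spec, X, obs.to_numpy(), n_restarts=3,
                                     seed=0)
        dec = sg.decompose(fit)
        assert dec.variance_shares["location"] > dec.variance_shares["age"]
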