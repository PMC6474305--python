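"""NB GLM fitting, likelihood kernel, prediction and adjusted D²."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mycocontext as mc
from mycocontext.nbglm import (
    DegenerateResponseError,
    NbGlmFit,
    SingularDesignError,
    nb_log_likelihood,
)


def _intercept(n):
    return pd.DataFrame({"intercept": np.ones(n)})


class TestFit:
    def test_constant_response_recovers_log_mean(self):
        fit = mc.fit_nb_glm(np.array([2, 2, 2, 2]), _intercept(4))
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2), abs=1e-6)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_perfect_proportionality_to_offset(self):
        y = np.array([1, 2, 3, 4])
        fit = mc.fit_nb_glm(y, _intercept(4), offset=np.log(y))
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-6)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_aic_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        y = rng.negative_binomial(2, 0.3, size=30)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=30)})
        fit = mc.fit_nb_glm(y, X)
        assert fit.aic == -2.0 * fit.log_likelihood + 2.0 * fit.p
        assert fit.p == 3  # two coefficients + theta
        assert (fit.fitted_means > 0).all()

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"intercept": np.ones(6), "dup": np.ones(6)})
        with pytest.raises(SingularDesignError, match="dup"):
            mc.fit_nb_glm(np.arange(1, 7), X)

    def test_all_zero_response_rejected(self):
        with pytest.raises(DegenerateResponseError):
            mc.fit_nb_glm(np.zeros(5, dtype=int), _intercept(5))

    def test_coefficient_recovery_on_simulated_data(self):
        # bias must be small at n = 2000 for known (beta, theta)
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.normal(size=n)
        beta = np.array([1.2, 0.6])
        theta = 1.5
        mu = np.exp(beta[0] + beta[1] * x)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        fit = mc.fit_nb_glm(y, pd.DataFrame({"intercept": 1.0, "x": x}))
        assert np.abs(fit.coefficients.to_numpy() - beta).max() < 0.05
        assert abs(np.log(fit.dispersion / theta)) < 0.15


class TestLogLikelihood:
    def test_matches_gamma_form_pointwise(self):
        # direct NB2 pmf: Gamma(y+theta)/(Gamma(theta) y!) (theta/(theta+mu))^theta (mu/(theta+mu))^y
        from math import lgamma, log

        y, mu, theta = 3, 3.0, 2.0
        direct = (
            lgamma(y + theta)
            - lgamma(theta)
            - lgamma(y + 1)
            + theta * log(theta / (theta + mu))
            + y * log(mu / (theta + mu))
        )
        assert nb_log_likelihood([y], [mu], theta) == pytest.approx(direct, abs=1e-12)

    def test_poisson_limit_at_zero_count(self):
        # P(0 | mu=1) -> e^-1 as theta -> inf
        assert nb_log_likelihood([0], [1.0], 1e8) == pytest.approx(-1.0, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_additive_over_observations(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 20, size=4)
        mu = rng.uniform(0.1, 10, size=4)
        theta = float(rng.uniform(0.2, 5))
        total = nb_log_likelihood(y, mu, theta)
        parts = sum(nb_log_likelihood([yi], [mi], theta) for yi, mi in zip(y, mu))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_likelihood([1], [0.0], 1.0)
        with pytest.raises(ValueError):
            nb_log_likelihood([1], [1.0], -1.0)


class TestPredict:
    def test_in_sample_identity(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=25)})
        y = rng.poisson(np.exp(0.5 + 0.3 * X["x"].to_numpy()))
        fit = mc.fit_nb_glm(y + 1, X)
        np.testing.assert_allclose(mc.predict_mean(fit, X), fit.fitted_means, rtol=1e-10)

    def test_unit_rate_equals_offset(self):
        fit = NbGlmFit(
            coefficients=pd.Series({"intercept": 0.0}),
            dispersion=1.0, log_likelihood=0.0, deviance=0.0, null_deviance=1.0,
            n=3, p=2, aic=4.0, fitted_means=np.ones(3),
            design_info={"columns": ["intercept"], "has_offset": True},
            converged=True,
        )
        L = np.array([10.0, 20.0, 40.0])
        np.testing.assert_allclose(
            mc.predict_mean(fit, pd.DataFrame({"intercept": np.ones(3)}), np.log(L)), L
        )

    def test_log_link_additivity_doubles_with_offset(self):
        fit = NbGlmFit(
            coefficients=pd.Series({"intercept": 0.3}),
            dispersion=1.0, log_likelihood=0.0, deviance=0.0, null_deviance=1.0,
            n=2, p=2, aic=4.0, fitted_means=np.ones(2),
            design_info={"columns": ["intercept"], "has_offset": True},
            converged=True,
        )
        X = pd.DataFrame({"intercept": np.ones(2)})
        base = mc.predict_mean(fit, X, np.log([2.0, 5.0]))
        doubled = mc.predict_mean(fit, X, np.log([4.0, 10.0]))
        np.testing.assert_allclose(doubled, 2 * base)

    def test_mismatched_columns_rejected(self):
        fit = NbGlmFit(
            coefficients=pd.Series({"intercept": 0.0}),
            dispersion=1.0, log_likelihood=0.0, deviance=0.0, null_deviance=1.0,
            n=2, p=2, aic=4.0, fitted_means=np.ones(2),
            design_info={"columns": ["intercept"], "has_offset": False},
            converged=True,
        )
        with pytest.raises(ValueError, match="columns"):
            mc.predict_mean(fit, pd.DataFrame({"other": np.ones(2)}))


class TestAdjustedD2:
    def _fit(self, deviance, null, n, p):
        return NbGlmFit(
            coefficients=pd.Series({"intercept": 0.0}),
            dispersion=1.0, log_likelihood=0.0, deviance=deviance,
            null_deviance=null, n=n, p=p, aic=0.0, fitted_means=np.ones(n),
            design_info={}, converged=True,
        )

    def test_hand_computed_value(self):
        # D2 = 0.6, adjusted = 1 - (20/16)*0.4 = 0.5
        assert mc.adjusted_d2(self._fit(40.0, 100.0, 21, 5)) == pytest.approx(0.5)

    def test_intercept_only_is_zero(self):
        assert mc.adjusted_d2(self._fit(70.0, 70.0, 30, 1)) == pytest.approx(0.0)

    def test_n_le_p_rejected(self):
        with pytest.raises(ValueError):
            mc.adjusted_d2(self._fit(1.0, 2.0, 4, 4))

    def test_negative_value_rendered_in_parentheses(self):
        val = mc.adjusted_d2(self._fit(49.0, 50.0, 12, 8))
        assert val < 0
        rendered = mc.format_adjusted_d2(-0.14)
        assert rendered == "0 (-0.14)"
        assert mc.format_adjusted_d2(0.54) == "0.54"


def test_noise_column_never_reduces_fit_quality():
    rng = np.random.default_rng(21)
    x = rng.normal(size=60)
    mu = np.exp(1.0 + 0.5 * x)
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    base = mc.fit_nb_glm(y, X)
    noisy = mc.fit_nb_glm(y, X.assign(junk=rng.normal(size=60)))
    # extra freedom cannot hurt the likelihood
    assert noisy.log_likelihood >= base.log_likelihood - 1e-6
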