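"""SARIMA engine: differencing, CSS likelihood, exact ML, AIC bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actirhythm import SarimaSpec, SarimaModel, difference, inverse_difference, css_loglik
from actirhythm.sarima import (
    NonInvertibleError,
    check_roots,
    css_innovations,
    expand_polynomials,
)


class TestDifference:
    def test_constant_series_doubly_differences_to_zero(self):
        y = np.full(165, 7.5)
        w = difference(y, 1, 1, 24)
        assert w.shape == (140,)
        np.testing.assert_allclose(w, 0.0)

    def test_linear_trend_first_difference_is_constant(self):
        y = np.arange(50, dtype=float)
        np.testing.assert_allclose(difference(y, 1, 0, 24), 1.0)

    def test_length_bookkeeping_165_to_140(self):
        y = np.random.default_rng(0).normal(size=165)
        assert len(difference(y, 1, 1, 24)) == 140

    def test_too_short_series_names_minimum_length(self):
        with pytest.raises(ValueError, match="minimum length is 26"):
            difference(np.ones(25), 1, 1, 24)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_with_stored_initials(self, seed):
        y = np.random.default_rng(seed).normal(50, 10, size=80)
        w = difference(y, 1, 1, 24)
        back = inverse_difference(w, y[:25], 1, 1, 24)
        np.testing.assert_allclose(back, y, atol=1e-9)


class TestCssLoglik:
    def test_white_noise_closed_form(self, rng):
        """With all orders zero, eps = w and the profiled MLE of sigma2 is
        mean(w^2); the likelihood at that point has the closed form
        -n/2 (log(2 pi s2) + 1)."""
        spec = SarimaSpec(0, 1, 0, 0, 1, 0, 24)
        w = rng.normal(0, 3, 140)
        s2 = float(w @ w) / len(w)
        ll = css_loglik(w, spec, np.zeros(0), s2)
        expected = -0.5 * len(w) * (math.log(2 * math.pi * s2) + 1)
        assert ll == pytest.approx(expected, rel=1e-12)
        # any other sigma2 is worse
        assert css_loglik(w, spec, np.zeros(0), 2 * s2) < ll
        assert css_loglik(w, spec, np.zeros(0), 0.5 * s2) < ll

    def test_pure_ar1_css_estimate_near_truth(self):
        """CSS on a long AR(1) recovers phi within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        phi = 0.6
        eps = rng.normal(0, 1, 6000)
        w = np.empty(6000)
        w[0] = eps[0]
        for t in range(1, 6000):
            w[t] = phi * w[t - 1] + eps[t]
        # wrap w into an undifferenced series the model will difference back
        spec = SarimaSpec(1, 0, 0, 0, 0, 0, 24)
        fit = SarimaModel(w, spec).fit(method="css")
        assert fit.params[0] == pytest.approx(phi, abs=0.05)

    def test_explosive_weights_raise(self, rng):
        """A non-invertible MA weight makes the innovation recursion blow
        up; the likelihood refuses to return a non-finite value."""
        spec = SarimaSpec(0, 1, 1, 0, 1, 0, 24)
        w = rng.normal(0, 1, 3000)
        with pytest.raises((NonInvertibleError, ValueError)):
            css_loglik(w, spec, np.array([1.7]), 1.0)

    def test_nonpositive_sigma2_rejected(self, rng):
        spec = SarimaSpec(0, 1, 0, 0, 1, 0, 24)
        with pytest.raises(ValueError):
            css_loglik(rng.normal(0, 1, 140), spec, np.zeros(0), 0.0)

    def test_innovations_depend_only_on_arguments(self, rng):
        spec = SarimaSpec(1, 1, 1, 0, 1, 1, 24)
        w = rng.normal(0, 1, 140)
        p = np.array([0.3, 0.2, 0.4])
        e1 = css_innovations(w, spec, p)
        e2 = css_innovations(w.copy(), spec, p.copy())
        np.testing.assert_array_equal(e1, e2)


class TestPolynomials:
    def test_multiplicative_expansion_orders(self):
        spec = SarimaSpec(1, 1, 1, 1, 1, 1, 24)
        a, b = expand_polynomials(spec, np.array([0.4, 0.3, 0.2, 0.1]))
        assert len(a) == 1 + 1 + 24  # (1 - 0.4 B)(1 - 0.2 B^24)
        assert len(b) == 1 + 1 + 24
        assert a[1] == pytest.approx(-0.4)
        assert a[24] == pytest.approx(-0.2)
        assert a[25] == pytest.approx(0.4 * 0.2)  # multiplicative cross term
        assert b[1] == pytest.approx(0.3)
        assert b[24] == pytest.approx(0.1)
        assert b[25] == pytest.approx(0.3 * 0.1)

    def test_check_roots_names_offending_polynomial(self):
        spec = SarimaSpec(1, 1, 1, 0, 1, 1, 24)
        assert check_roots(spec, np.array([0.4, 0.3, 0.5])) is None
        assert check_roots(spec, np.array([1.2, 0.3, 0.5])) == "non-seasonal AR"
        assert check_roots(spec, np.array([0.4, 1.2, 0.5])) == "non-seasonal MA"
        assert check_roots(spec, np.array([0.4, 0.3, 1.2])) == "seasonal MA"


class TestFit:
    def test_all_zero_orders_closed_form_aic(self, hourly_series):
        """(0,1,0)(0,1,0): no free weights, white-noise likelihood, k = 1."""
        spec = SarimaSpec(0, 1, 0, 0, 1, 0, 24)
        fit = SarimaModel(hourly_series.values, spec).fit()
        w = difference(hourly_series.values, 1, 1, 24)
        s2 = float(w @ w) / len(w)
        expected_ll = -0.5 * len(w) * (math.log(2 * math.pi * s2) + 1)
        assert fit.converged
        assert fit.loglik == pytest.approx(expected_ll, rel=1e-10)
        assert fit.aic == pytest.approx(2 * 1 - 2 * expected_ll, rel=1e-10)

    def test_aic_identity_across_specs(self, hourly_series):
        for spec in [SarimaSpec(1, 1, 0, 0, 1, 0, 24),
                     SarimaSpec(1, 1, 1, 0, 1, 1, 24),
                     SarimaSpec(0, 1, 1, 1, 1, 1, 24)]:
            fit = SarimaModel(hourly_series.values, spec).fit()
            k = spec.p + spec.q + spec.P + spec.Q + 1
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, rel=1e-12)

    def test_likelihood_never_below_zero_start(self, hourly_series):
        spec = SarimaSpec(2, 1, 2, 0, 1, 1, 24)
        model = SarimaModel(hourly_series.values, spec)
        fit = model.fit()
        ll_zero = model.loglik(np.zeros(spec.n_params))
        assert fit.loglik >= ll_zero - 1e-6

    def test_nested_model_loglik_dominance(self, hourly_series):
        small = SarimaModel(hourly_series.values, SarimaSpec(0, 1, 0, 0, 1, 0, 24)).fit()
        big = SarimaModel(hourly_series.values, SarimaSpec(1, 1, 1, 0, 1, 1, 24)).fit()
        assert big.loglik >= small.loglik - 1e-6

    def test_scale_equivariance(self, hourly_series):
        """Rescaling the series leaves the ARMA weights unchanged and scales
        sigma2 by c^2 (the Gaussian likelihood is scale-equivariant)."""
        spec = SarimaSpec(1, 1, 1, 0, 1, 1, 24)
        f1 = SarimaModel(hourly_series.values, spec).fit()
        c = 3.7
        f2 = SarimaModel(c * hourly_series.values, spec).fit()
        np.testing.assert_allclose(f1.params, f2.params, atol=2e-3)
        assert f2.sigma2 == pytest.approx(c ** 2 * f1.sigma2, rel=1e-3)

    def test_parameter_recovery_long_series(self, model22_spec, model22_weights):
        from actirhythm.synthetic import DEFAULT_PROFILE, simulate_hourly_series

        y = simulate_hourly_series(model22_spec, model22_weights, DEFAULT_PROFILE,
                                   5.0, 5000, seed=2, clip_negative=False)
        fit = SarimaModel(y.values, model22_spec).fit()
        truth = np.array([0.4, 0.3, 0.5])
        assert np.abs(fit.params - truth).max() <= 0.1
        assert fit.converged

    def test_too_short_series_rejected(self):
        spec = SarimaSpec(1, 1, 1, 0, 1, 1, 24)
        with pytest.raises(ValueError, match="minimum length"):
            SarimaModel(np.ones(30), spec)

    def test_results_serialization_keys(self, hourly_series):
        fit = SarimaModel(hourly_series.values, SarimaSpec(1, 1, 1, 1, 1, 1, 24)).fit()
        d = fit.to_dict()
        assert set(d["weights"]) == {"ar.L1", "ma.L1", "ar.S.L24", "ma.S.L24"}
        assert d["spec"] == [1, 1, 1, 1, 1, 1, 24]
        for key in ("sigma2", "loglik", "aic", "converged"):
            assert key in d


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [(-1, 1, 0, 0, 1, 0, 24), (1, 1, 0, 0, 1, 0, 0)])
    def test_invalid_orders_rejected(self, bad):
        with pytest.raises(ValueError):
            SarimaSpec(*bad)

    def test_weights_mapping_validates_keys(self, model22_spec):
        with pytest.raises(ValueError, match="missing"):
            model22_spec.weights_from_mapping({"ar1": 0.4})
        with pytest.raises(ValueError, match="not present"):
            model22_spec.weights_from_mapping(
                {"ar1": 0.4, "ma1": 0.3, "sma1": 0.5, "sar1": 0.2})
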