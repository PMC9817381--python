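"""Synthetic cohort generator: determinism, conservation, calibrated rates."""

import dataclasses

import numpy as np
import pytest

from actirhythm import SarimaSpec
from actirhythm.preprocess import (
    aggregate_hourly,
    apply_exclusion_rule,
    detect_nonwear,
    zero_runs,
)
from actirhythm.sarima import NonInvertibleError, difference
from actirhythm.selection import FeatureVector
from actirhythm.synthetic import (
    DEFAULT_PROFILE,
    CohortConfig,
    GapModel,
    OutcomeModel,
    disaggregate_to_minutes,
    generate_cohort,
    inject_nonwear,
    simulate_hourly_series,
    simulate_scores,
)


class TestSimulateHourly:
    def test_zero_weights_zero_noise_flat_profile_gives_constant(self):
        spec = SarimaSpec(0, 1, 0, 0, 1, 0, 24)
        profile = np.full(24, 80.0)
        h = simulate_hourly_series(spec, {}, profile, 0.0, 165, seed=1)
        np.testing.assert_allclose(h.values, 80.0)

    def test_seed_reproducibility(self, model22_spec, model22_weights):
        h1 = simulate_hourly_series(model22_spec, model22_weights,
                                    DEFAULT_PROFILE, 2.0, 165, seed=42)
        h2 = simulate_hourly_series(model22_spec, model22_weights,
                                    DEFAULT_PROFILE, 2.0, 165, seed=42)
        np.testing.assert_array_equal(h1.values, h2.values)

    def test_nonstationary_weights_rejected_with_diagnostic(self, model22_spec):
        with pytest.raises(NonInvertibleError, match="non-seasonal AR"):
            simulate_hourly_series(model22_spec,
                                   {"ar1": 1.1, "ma1": 0.3, "sma1": 0.5},
                                   DEFAULT_PROFILE, 2.0, 165, seed=0)

    def test_differenced_series_matches_theoretical_acf(
            self, model22_spec, model22_weights):
        """The double difference of the simulated series is the configured
        ARMA process: its sample ACF matches the closed-form ARMA
        autocovariance (statsmodels arma_acf oracle) within Monte-Carlo
        error at n = 2000."""
        from statsmodels.tsa.arima_process import arma_acf
        from actirhythm.sarima import expand_polynomials

        h = simulate_hourly_series(model22_spec, model22_weights,
                                   DEFAULT_PROFILE, 5.0, 2000, seed=3,
                                   clip_negative=False)
        w = difference(h.values, 1, 1, 24)
        params = model22_spec.weights_from_mapping(model22_weights)
        a, b = expand_polynomials(model22_spec, params)
        theo = arma_acf(a, b, lags=30)
        samp = np.array([
            np.corrcoef(w[:-k], w[k:])[0, 1] if k else 1.0 for k in range(30)
        ])
        for lag in (1, 2, 24, 25):
            assert samp[lag] == pytest.approx(theo[lag], abs=0.07)

    def test_profile_validated(self, model22_spec, model22_weights):
        with pytest.raises(ValueError, match="profile"):
            simulate_hourly_series(model22_spec, model22_weights,
                                   np.ones(23), 2.0, 165, seed=0)


class TestDisaggregate:
    def test_hour_value_conserved_and_nonnegative(self, rng):
        from actirhythm.preprocess import HourlySeries

        hourly = HourlySeries("p", np.array([60.0, 0.0, 123.4]),
                              window_start="2022-01-02")
        minutes = disaggregate_to_minutes(hourly, rng)
        assert len(minutes) == 180
        assert (minutes.met >= 0).all()
        np.testing.assert_allclose(minutes.met[:60].sum(), 60.0, rtol=1e-12)
        np.testing.assert_array_equal(minutes.met[60:120], 0.0)
        np.testing.assert_allclose(minutes.met[120:].sum(), 123.4, rtol=1e-12)

    def test_roundtrip_through_hourly_aggregation(self, model22_spec,
                                                  model22_weights, rng):
        h = simulate_hourly_series(model22_spec, model22_weights,
                                   DEFAULT_PROFILE, 1.0, 48, seed=9, floor=30.0)
        minutes = disaggregate_to_minutes(h, rng)
        back = aggregate_hourly(minutes, window_start=minutes.start, n_hours=48)
        np.testing.assert_allclose(back.values, h.values, rtol=1e-10)

    def test_negative_hourly_input_rejected(self, rng):
        from actirhythm.preprocess import HourlySeries

        with pytest.raises(ValueError):
            HourlySeries("p", np.array([-1.0, 5.0]))


class TestInjectNonwear:
    def test_zero_rates_leave_series_unchanged(self, minute_series_factory, rng):
        s = minute_series_factory(np.ones(1440))
        out = inject_nonwear(s, GapModel(short_rate_per_day=0.0), rng)
        np.testing.assert_array_equal(out.met, s.met)

    def test_forced_long_gap_triggers_downstream_exclusion(
            self, minute_series_factory, rng):
        s = minute_series_factory(np.full(60 * 48, 1.5))
        out = inject_nonwear(s, GapModel(short_rate_per_day=0.0,
                                         long_rate_per_day=0.0), rng,
                             force_long_gap=True)
        report = apply_exclusion_rule(detect_nonwear(out))
        assert report.excluded
        assert report.longest_gap_min > 30

    def test_short_gap_count_matches_configured_rate(self, minute_series_factory):
        """Expected number of injected short runs over many seeds matches
        the Poisson rate x duration within Monte-Carlo tolerance."""
        rate, days, n_rep = 2.0, 2.0, 120
        counts = []
        for seed in range(n_rep):
            s = minute_series_factory(np.full(int(1440 * days), 1.5))
            out = inject_nonwear(
                s, GapModel(short_rate_per_day=rate,
                            short_length_range=(3, 10)), seed)
            counts.append(len(zero_runs(out.met)))
        mean = np.mean(counts)
        lam = rate * days
        tol = 3 * np.sqrt(lam / n_rep)
        assert abs(mean - lam) < tol + 0.15  # slack for run merging


class TestSimulateScores:
    def test_zero_noise_zero_features_returns_intercepts(self):
        outcome = OutcomeModel(noise_sd=0.0)
        scores = simulate_scores(FeatureVector(), outcome, seed=0)
        for scale, (intercept, _) in outcome.betas.items():
            assert scores[scale] == pytest.approx(intercept)

    def test_linear_in_features_without_noise(self):
        outcome = OutcomeModel(noise_sd=0.0)
        fv = FeatureVector(ar1=0.5, sma1=-0.2)
        scores = simulate_scores(fv, outcome, seed=0)
        for scale, (b0, bs) in outcome.betas.items():
            assert scores[scale] == pytest.approx(b0 + 0.5 * bs[0] - 0.2 * bs[7])

    def test_clipping_to_scale_range_when_enabled(self):
        betas = {"bdi": (100.0, tuple([0.0] * 8))}
        out_clip = OutcomeModel(betas=betas, noise_sd=0.0, clip_to_range=True)
        out_free = OutcomeModel(betas=betas, noise_sd=0.0, clip_to_range=False)
        assert simulate_scores(FeatureVector(), out_clip, 0)["bdi"] == 63.0
        assert simulate_scores(FeatureVector(), out_free, 0)["bdi"] == 100.0


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self):
        cfg = dataclasses.replace(CohortConfig(), n_participants=4, seed=7)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for p1, p2 in zip(c1.participants, c2.participants):
            np.testing.assert_array_equal(p1.minute_series.met,
                                          p2.minute_series.met)
            assert p1.scores == p2.scores
            np.testing.assert_array_equal(p1.true_features.to_array(),
                                          p2.true_features.to_array())
        assert c1.manifest().equals(c2.manifest())

    def test_different_seeds_differ(self):
        base = dataclasses.replace(CohortConfig(), n_participants=2)
        c1 = generate_cohort(dataclasses.replace(base, seed=1))
        c2 = generate_cohort(dataclasses.replace(base, seed=2))
        assert not np.array_equal(c1.participants[0].minute_series.met,
                                  c2.participants[0].minute_series.met)

    def test_exact_long_gap_assignment(self):
        cfg = dataclasses.replace(
            CohortConfig.study_design(seed=5), n_participants=12,
            n_long_gap_participants=4)
        cohort = generate_cohort(cfg)
        excluded = sum(
            apply_exclusion_rule(detect_nonwear(p.minute_series)).excluded
            for p in cohort.participants)
        assert excluded == 4

    def test_minute_series_covers_configured_window(self):
        cfg = dataclasses.replace(CohortConfig(), n_participants=1, seed=0)
        cohort = generate_cohort(cfg)
        assert len(cohort.participants[0].minute_series) == 165 * 60

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig.study_design(seed=3)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = CohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
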