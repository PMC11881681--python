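"""Data-generating mechanism: covariates, thresholding, outcomes, coarsening."""

import math

import numpy as np
import pytest
from scipy import stats

from coarsemi.simulate import (CORRELATION_SETS, ScenarioConfig,
                               TrueCoefficients, apply_coarsening,
                               calibrate_gamma_intercepts, discretize_x,
                               gen_covariates, gen_outcome_continuous,
                               gen_outcome_survival, linear_predictor,
                               scenario_grid, simulate_replicate)


class TestCovariates:
    def test_zero_correlation_case(self, rng):
        cfg = ScenarioConfig(n_obs=100_000)
        x, z1, z2 = gen_covariates(cfg, rng)
        n = cfg.n_obs
        for a, b in [(x, z1), (x, z2), (z1, z2)]:
            assert abs(np.corrcoef(a, b)[0, 1]) < 3 / math.sqrt(n)

    def test_requested_correlations_recovered(self, rng):
        cfg = ScenarioConfig(n_obs=100_000, rho_xz1=0.7, rho_xz2=0.3,
                             rho_z1z2=0.0)
        x, z1, z2 = gen_covariates(cfg, rng)
        assert abs(np.corrcoef(x, z1)[0, 1] - 0.7) < 0.01
        assert abs(np.corrcoef(x, z2)[0, 1] - 0.3) < 0.01
        # standard-normal marginals
        assert abs(x.mean()) < 0.02 and abs(x.std() - 1) < 0.02

    def test_degenerate_n_one(self, rng):
        cfg = ScenarioConfig(n_obs=1)
        x, z1, z2 = gen_covariates(cfg, rng)
        assert np.isfinite([x, z1, z2]).all()

    def test_invalid_correlation_matrix_rejected(self, rng):
        cfg = ScenarioConfig(rho_xz1=0.99, rho_xz2=-0.99, rho_z1z2=0.99)
        with pytest.raises(ValueError):
            gen_covariates(cfg, rng)


class TestDiscretize:
    def test_boundary_inclusive_at_median(self):
        assert discretize_x([0.0], (0.5, 0.25, 0.25))[0] == "a"

    def test_uniform_thresholds_against_quantile_oracle(self):
        # Phi^-1(1/3) ~ -0.4307, Phi^-1(2/3) ~ +0.4307
        probs = (1 / 3, 1 / 3, 1 / 3)
        assert list(discretize_x([-1.0, 0.0, 1.0], probs)) == ["a", "b", "c"]
        t = stats.norm.ppf(1 / 3)
        assert discretize_x([t], probs)[0] == "a"
        assert discretize_x([t + 1e-9], probs)[0] == "b"

    def test_skewed_frequencies_recovered(self, rng):
        probs = (1 / 2, 1 / 3, 1 / 6)
        labels = discretize_x(rng.standard_normal(100_000), probs)
        for lab, p in zip("abc", probs):
            assert abs((labels == lab).mean() - p) < 0.01


class TestOutcomes:
    def test_linear_predictor_examples(self):
        b = TrueCoefficients.defaults("continuous")
        assert linear_predictor(["b"], [0.0], [0.0], b)[0] == pytest.approx(0.5)
        assert linear_predictor(["a"], [0.0], [0.0], b)[0] == pytest.approx(0.0)
        assert linear_predictor(["c"], [1.0], [-1.0], b)[0] == pytest.approx(1.0)

    def test_continuous_noise_is_standard_normal(self, rng):
        b = TrueCoefficients.defaults("continuous")
        y = gen_outcome_continuous(["a"] * 200_000, np.zeros(200_000),
                                   np.zeros(200_000), b, rng)
        assert abs(y.mean()) < 0.01 and abs(y.std() - 1.0) < 0.01

    def test_survival_rate_and_censoring(self, rng):
        b = TrueCoefficients.defaults("survival")  # baseline rate 0.1
        n = 200_000
        time, status = gen_outcome_survival(["a"] * n, np.zeros(n),
                                            np.zeros(n), b, rng)
        assert time.max() <= 10.0
        # censored rows carry the censoring time, supported on [5, 10]
        assert time[status == 0].min() >= 5.0
        # event-time mean 1/rate = 10; estimate from the uncensored tail rate
        # instead: P(event before 5) = 1 - exp(-0.5)
        p5 = ((time < 5) & (status == 1)).mean()
        assert abs(p5 - (1 - math.exp(-0.5))) < 0.01

    def test_survival_intercept_is_log_point_one(self):
        assert TrueCoefficients.defaults("survival").beta0 == \
            pytest.approx(math.log(0.1))


class TestGammaCalibration:
    def test_closed_form_no_slopes(self):
        g = calibrate_gamma_intercepts((0.2, 0.4, 0.4),
                                       gamma_slopes=(0, 0, 0, 0))
        assert g.g1[0] == pytest.approx(math.log(2), abs=1e-8)
        assert g.g2[0] == pytest.approx(math.log(2), abs=1e-8)

    def test_degenerate_zero_missing_no_slopes(self):
        g = calibrate_gamma_intercepts((0.0, 0.4, 0.6),
                                       gamma_slopes=(0, 0, 0, 0))
        assert g.drop_missing
        assert g.g2[0] - g.g1[0] == pytest.approx(math.log(0.6 / 0.4))

    @pytest.mark.parametrize("targets", [(0.2, 0.4, 0.4), (0.0, 0.4, 0.6)])
    def test_monte_carlo_recovery_with_slopes(self, targets, rng):
        g = calibrate_gamma_intercepts(targets, gamma_slopes=(1, 0, 0, 1))
        z1 = rng.standard_normal(1_000_000)
        z2 = rng.standard_normal(1_000_000)
        achieved = g.pattern_probs(z1, z2).mean(axis=0)
        np.testing.assert_allclose(achieved, targets, atol=0.002)

    def test_unattainable_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gamma_intercepts((1.0, 0.0, 0.0))


class TestApplyCoarsening:
    def test_rules(self, rng):
        g = calibrate_gamma_intercepts((0.2, 0.4, 0.4))
        labels = np.array(["a", "b", "c"] * 2000, dtype=object)
        z = np.zeros(6000)
        x_obs, r = apply_coarsening(labels, z, z, g, rng)
        for lab, s, ri in zip(labels, x_obs, r):
            if ri == 0:
                assert s.is_missing
            elif ri == 1:
                assert s.is_observed and s.label == lab
            else:
                if lab == "a":
                    # exempt from coarsening: the group identifies the value
                    assert s.is_observed and s.label == "a"
                else:
                    assert s.sorted_labels() == ("b", "c")

    def test_coarsened_rows_are_b_or_c(self, rng):
        cfg = ScenarioConfig(n_obs=5000, coarsen_probs=(0.2, 0.4, 0.4))
        rep = simulate_replicate(cfg, rng)
        coarsened = [i for i, s in enumerate(rep.dataset.x) if s.is_coarsened]
        assert len(coarsened) > 0
        assert set(rep.x_true[coarsened]) <= {"b", "c"}
        # true label always compatible with the observation
        for s, lab in zip(rep.dataset.x, rep.x_true):
            assert lab in s

    @pytest.mark.parametrize("targets", [(0.2, 0.4, 0.4), (0.0, 0.4, 0.6)])
    def test_empirical_pattern_probabilities(self, targets, rng):
        g = calibrate_gamma_intercepts(targets, gamma_slopes=(1, 0, 0, 1))
        z1 = rng.standard_normal(100_000)
        z2 = rng.standard_normal(100_000)
        labels = np.array(["b"] * 100_000, dtype=object)
        _, r = apply_coarsening(labels, z1, z2, g, rng)
        freqs = np.bincount(r, minlength=3) / len(r)
        np.testing.assert_allclose(freqs, targets, atol=0.01)


class TestGrid:
    def test_full_factorial_size(self):
        assert len(scenario_grid()) == 216

    def test_excluded_correlation_cells(self):
        assert len(CORRELATION_SETS) == 6
        assert all(not (c[0] == 0.0 and c[1] == 0.3) for c in CORRELATION_SETS)

    def test_grid_covers_both_outcomes_and_coarsening_settings(self):
        grid = scenario_grid()
        assert {g.outcome_kind for g in grid} == {"continuous", "survival"}
        assert {g.coarsen_probs for g in grid} == \
            {(0.0, 0.4, 0.6), (0.2, 0.4, 0.4)}
        assert {g.effect_multiplier for g in grid} == {0.5, 1.0, 2.0}


class TestReplicateDeterminism:
    def test_same_seed_same_data(self):
        cfg = ScenarioConfig(n_obs=200)
        a = simulate_replicate(cfg, 5)
        b = simulate_replicate(cfg, 5)
        np.testing.assert_array_equal(a.dataset.y, b.dataset.y)
        np.testing.assert_array_equal(a.r, b.r)
        assert [s.subset for s in a.dataset.x] == \
            [s.subset for s in b.dataset.x]
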