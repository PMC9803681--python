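"""Psychometric fitting: recovery, AIC selection, SD derivation, bootstrap."""

import dataclasses

import numpy as np
import pytest

from durleak.psychometric import (
    BETA_MAX,
    BinnedResponses,
    bootstrap_ci,
    derive_sd,
    fit_condition,
    fit_logistic,
    logistic_p,
    select_by_aic,
)

LEVELS = np.array([-1.2, -0.8, -0.4, 0.4, 0.8, 1.2])


def generated(pse, slope, lapse=0.0, n_per=200, levels=LEVELS, seed=0):
    rng = np.random.default_rng(seed)
    p = logistic_p(levels, pse, slope, lapse)
    n = np.full(levels.size, n_per)
    m = rng.binomial(n, p)
    return BinnedResponses(levels, n, m)


class TestBinnedResponses:
    def test_unsorted_levels_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BinnedResponses([0.5, -0.5], [10, 10], [5, 5])

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            BinnedResponses([-0.5, 0.5], [10, 10], [5, 11])


class TestFitLogistic:
    def test_parameter_recovery_with_ci(self):
        data = generated(pse=0.0, slope=4.0, n_per=200, seed=11)
        fit = fit_logistic(data)
        fit = bootstrap_ci(data, fit, n_boot=200, seed=5)
        assert fit.converged
        assert fit.ci_pse[0] <= 0.0 <= fit.ci_pse[1]
        assert fit.slope == pytest.approx(4.0, rel=0.25)

    def test_flat_data_flagged_with_near_zero_slope(self):
        data = BinnedResponses(LEVELS, np.full(6, 30), np.full(6, 15))
        fit = fit_logistic(data)
        assert abs(fit.slope) < 0.05
        assert "flat_data" in fit.flags

    def test_perfect_step_hits_slope_bound(self):
        n = np.full(6, 30)
        m = np.where(LEVELS < 0, 0, 30)
        fit = fit_logistic(BinnedResponses(LEVELS, n, m))
        assert abs(fit.slope) >= 0.999 * BETA_MAX
        assert "slope_at_bound" in fit.flags

    def test_all_same_response_flagged_degenerate(self):
        fit = fit_logistic(BinnedResponses(LEVELS, np.full(6, 30), np.full(6, 30)))
        assert "degenerate_data" in fit.flags

    def test_too_few_levels_rejected(self):
        data = BinnedResponses([-1.0, 1.0], [30, 30], [5, 25])
        with pytest.raises(ValueError, match="levels"):
            fit_logistic(data)
        data3 = BinnedResponses([-1.0, 0.0, 1.0], [30, 30, 30], [5, 15, 25])
        with pytest.raises(ValueError, match="levels"):
            fit_logistic(data3, with_lapse=True)

    def test_loglik_at_fit_beats_generating_params(self):
        # optimizer sanity: the MLE cannot be worse than the truth
        for seed in range(5):
            data = generated(pse=0.2, slope=3.0, seed=seed, n_per=50)
            fit = fit_logistic(data)

            def ll(pse, slope):
                p = np.clip(logistic_p(data.levels, pse, slope), 1e-9, 1 - 1e-9)
                return float(
                    np.sum(data.m * np.log(p) + (data.n - data.m) * np.log1p(-p))
                )

            assert ll(fit.pse, fit.slope) >= ll(0.2, 3.0) - 1e-6

    def test_negative_slope_recovered(self):
        data = generated(pse=0.0, slope=-3.0, n_per=200, seed=2)
        fit = fit_logistic(data)
        assert fit.slope == pytest.approx(-3.0, rel=0.3)

    def test_fitted_curve_monotone_within_lapse_bounds(self):
        data = generated(pse=0.1, slope=2.5, lapse=0.05, n_per=100, seed=3)
        fit = fit_logistic(data, with_lapse=True)
        x = np.linspace(-3, 3, 200)
        p = logistic_p(x, fit.pse, fit.slope, fit.lapse)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all(p >= fit.lapse - 1e-12)
        assert np.all(p <= 1 - fit.lapse + 1e-12)


class TestAicSelection:
    def test_strictly_lower_aic_wins(self):
        data = generated(pse=0.0, slope=4.0, seed=1)
        f0 = fit_logistic(data)
        f1 = dataclasses.replace(fit_logistic(data, with_lapse=True))
        winner = select_by_aic(
            dataclasses.replace(f0, aic=f1.aic + 3.0), f1
        )
        assert winner is f1

    def test_tie_goes_to_fewer_parameters(self):
        data = generated(pse=0.0, slope=4.0, seed=1)
        f0 = fit_logistic(data)
        f1 = fit_logistic(data, with_lapse=True)
        winner = select_by_aic(f0, dataclasses.replace(f1, aic=f0.aic))
        assert winner is f0

    def test_lapse_free_generator_mostly_selects_nolapse(self):
        picks = []
        for seed in range(50):
            data = generated(pse=0.0, slope=4.0, lapse=0.0, n_per=100, seed=seed)
            f0 = fit_logistic(data)
            f1 = fit_logistic(data, with_lapse=True)
            picks.append(not select_by_aic(f0, f1).has_lapse)
        assert np.mean(picks) >= 0.8

    def test_nesting_aic_gap_bounded_when_lapse_zero(self):
        # with lambda-hat = 0 the lapse model matches the no-lapse loglik,
        # so its AIC exceeds by at most the 2-point parameter penalty
        for seed in range(10):
            data = generated(pse=0.0, slope=4.0, n_per=100, seed=seed)
            f0 = fit_logistic(data)
            f1 = fit_logistic(data, with_lapse=True)
            if f1.lapse < 1e-6:
                assert f1.aic <= f0.aic + 2.0 + 1e-6


class TestDeriveSd:
    def test_unit_inversion(self):
        assert derive_sd(np.pi / np.sqrt(3)) == pytest.approx(1.0)

    def test_scaling_law(self):
        assert derive_sd(8.0) == pytest.approx(derive_sd(4.0) / 2)

    def test_sign_invariance(self):
        assert derive_sd(-4.0) == derive_sd(4.0)

    def test_zero_slope_is_nan(self):
        assert np.isnan(derive_sd(0.0))

    def test_recovery_of_latent_sd(self):
        latent_sd = 0.35
        slope = np.pi / (latent_sd * np.sqrt(3))
        data = generated(pse=0.0, slope=slope, n_per=200, seed=4)
        fit = fit_logistic(data)
        assert fit.sd == pytest.approx(latent_sd, rel=0.15)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        data = generated(pse=0.0, slope=4.0, n_per=50, seed=7)
        fit = fit_logistic(data)
        a = bootstrap_ci(data, fit, n_boot=50, seed=42)
        b = bootstrap_ci(data, fit, n_boot=50, seed=42)
        assert a.ci_pse == b.ci_pse and a.ci_slope == b.ci_slope

    def test_zero_nboot_rejected(self):
        data = generated(pse=0.0, slope=4.0, seed=7)
        fit = fit_logistic(data)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(data, fit, n_boot=0)

    def test_interval_bounds_ordered_and_cover_estimate(self):
        data = generated(pse=0.0, slope=4.0, n_per=100, seed=9)
        fit = bootstrap_ci(data, fit_logistic(data), n_boot=200, seed=1)
        assert fit.ci_pse[0] < fit.ci_pse[1]
        assert fit.ci_slope[0] < fit.ci_slope[1]

    def test_slope_ci_coverage(self):
        # 95% parametric-bootstrap CI should cover the generating slope in
        # roughly 95% of replicates (accept 88-99% at 100 replicates)
        covered = 0
        for rep in range(100):
            data = generated(pse=0.0, slope=4.0, n_per=30, seed=1000 + rep)
            fit = fit_logistic(data)
            fit = bootstrap_ci(data, fit, n_boot=200, seed=rep)
            if fit.ci_slope[0] <= 4.0 <= fit.ci_slope[1]:
                covered += 1
        assert 88 <= covered <= 99


class TestFitCondition:
    def test_returns_ci_and_selected_model(self):
        data = generated(pse=0.1, slope=3.0, n_per=60, seed=21)
        fit = fit_condition(data, n_boot=100, seed=2)
        assert fit.ci_slope is not None
        assert fit.n_boot == 100
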