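"""Leaking-factor MLE: likelihood oracle, recovery, goodness of fit."""

import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from durleak.leakfit import ComboCounts, chi_square_gof, fit_k, log_likelihood_k
from durleak.model import LeakParams, p_second_longer

from conftest import counts_from_k, full_design_combos


def per_trial_oracle(counts: ComboCounts, k: float, variant: str) -> float:
    """Independent check: sum Bernoulli log-likelihoods trial by trial, then
    add the binomial combinatorial constant."""
    total = 0.0
    params = LeakParams(variant, k)
    for d1, d2, n, m in zip(counts.d1, counts.d2, counts.n, counts.m):
        phi = p_second_longer(counts.t, d1, counts.t, d2, params)
        for trial in range(n):
            total += math.log(phi) if trial < m else math.log(1.0 - phi)
        total += math.log(math.comb(n, m))
    return total


def random_small_counts(rng):
    s = rng.integers(2, 5)
    durs = rng.uniform(0.1, 4.0, size=(s, 2))
    durs[:, 1] = durs[:, 0] + rng.uniform(0.05, 2.0, size=s)  # force d1 != d2
    n = rng.integers(1, 11, size=s)
    m = rng.integers(0, n + 1)
    return ComboCounts(d1=durs[:, 0], d2=durs[:, 1], n=n, m=m, t=1.0)


class TestComboCounts:
    def test_equal_distractors_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ComboCounts([0.3, 0.7], [0.3, 1.5], [30, 30], [10, 10])

    def test_single_combo_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ComboCounts([0.3], [0.7], [30], [10])


class TestLogLikelihood:
    def test_matches_per_trial_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            counts = random_small_counts(rng)
            k = rng.uniform(0.01, 0.99)
            got = log_likelihood_k(counts, k, "leaking")
            assert got == pytest.approx(per_trial_oracle(counts, k, "leaking"), abs=1e-9)

    def test_matches_oracle_ricker(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = random_small_counts(rng)
            k = rng.uniform(0.1, 5.0)
            got = log_likelihood_k(counts, k, "ricker")
            assert got == pytest.approx(per_trial_oracle(counts, k, "ricker"), abs=1e-9)

    def test_bounded_by_saturated_model(self):
        # binomial likelihood peaks when predicted p equals observed m/n
        counts = counts_from_k(0.4, rng=np.random.default_rng(0))
        frac = np.clip(counts.m / counts.n, 1e-9, 1 - 1e-9)
        saturated = float(
            np.sum(
                counts.m * np.log(frac)
                + (counts.n - counts.m) * np.log1p(-frac)
                + [math.log(math.comb(n, m)) for n, m in zip(counts.n, counts.m)]
            )
        )
        for k in np.linspace(0.01, 0.99, 20):
            assert log_likelihood_k(counts, k, "leaking") <= saturated + 1e-9

    def test_relabeling_symmetry(self):
        combos = full_design_combos()
        d1 = np.array([c[0] for c in combos])
        d2 = np.array([c[1] for c in combos])
        n = np.full(12, 30)
        m = np.full(12, 15)
        a = ComboCounts(d1, d2, n, m)
        b = ComboCounts(d2, d1, n, m)  # swap every pair
        for k in (0.2, 0.5, 0.8):
            assert log_likelihood_k(a, k) == pytest.approx(
                log_likelihood_k(b, k), abs=1e-9
            )

    def test_out_of_range_k_rejected(self):
        counts = counts_from_k(0.5)
        with pytest.raises(ValueError):
            log_likelihood_k(counts, 1.5, "leaking")


class TestFitK:
    def test_noise_free_recovery(self):
        # expected proportions on a fine rational grid stand in for n -> inf
        counts = counts_from_k(0.5, n_per=100_000)
        fit = fit_k(counts, "leaking")
        assert fit.converged
        assert fit.k_hat == pytest.approx(0.5, abs=0.01)

    def test_noise_free_recovery_ricker(self):
        counts = counts_from_k(0.4, variant="ricker", n_per=100_000)
        fit = fit_k(counts, "ricker")
        assert fit.converged
        assert fit.k_hat == pytest.approx(0.4, abs=0.02)

    def test_uninformative_counts_fit_chance(self):
        combos = full_design_combos()
        counts = ComboCounts(
            d1=[c[0] for c in combos],
            d2=[c[1] for c in combos],
            n=np.full(12, 30),
            m=np.full(12, 15),
        )
        fit = fit_k(counts, "leaking")
        # best leaking account of 50/50 everywhere: no leak (k at the lower
        # boundary), predicted probabilities all 0.5
        assert fit.k_hat < 0.05 or "flat_likelihood" in fit.flags
        phi = p_second_longer(
            1.0, counts.d1, 1.0, counts.d2, LeakParams("leaking", fit.k_hat)
        )
        assert np.allclose(phi, 0.5, atol=0.02)

    def test_invariant_to_combo_order_and_splitting(self):
        rng = np.random.default_rng(5)
        counts = counts_from_k(0.35, rng=rng)
        perm = rng.permutation(counts.n_combos)
        shuffled = ComboCounts(
            counts.d1[perm], counts.d2[perm], counts.n[perm], counts.m[perm]
        )
        assert fit_k(shuffled).k_hat == pytest.approx(fit_k(counts).k_hat, abs=1e-6)

        # split the first combo's counts into two identical combos
        half_n = counts.n[0] // 2
        half_m = counts.m[0] // 2
        split = ComboCounts(
            np.r_[counts.d1, counts.d1[0]],
            np.r_[counts.d2, counts.d2[0]],
            np.r_[half_n, counts.n[1:], counts.n[0] - half_n],
            np.r_[half_m, counts.m[1:], counts.m[0] - half_m],
        )
        assert fit_k(split).k_hat == pytest.approx(fit_k(counts).k_hat, abs=1e-6)

    def test_recovery_across_cohort(self):
        rng = np.random.default_rng(99)
        k_true = rng.uniform(0.05, 0.95, size=15)
        k_hat = [fit_k(counts_from_k(k, rng=rng)).k_hat for k in k_true]
        r, _ = pearsonr(k_true, k_hat)
        assert r >= 0.8

    def test_ricker_fit_reproduces_repulsion(self):
        # generator in the repulsive regime: response association with
        # d2 - d1 must be negative in fit as in truth
        counts = counts_from_k(0.3, variant="ricker", n_per=100_000)
        fit = fit_k(counts, "ricker")
        phi = p_second_longer(
            1.0, counts.d1, 1.0, counts.d2, LeakParams("ricker", fit.k_hat)
        )
        diff = counts.d2 - counts.d1
        truth_assoc = pearsonr(diff, counts.m / counts.n)[0]
        fit_assoc = pearsonr(diff, phi)[0]
        assert truth_assoc < 0 and fit_assoc < 0

    def test_leaking_probabilities_monotone_in_difference(self):
        combos = sorted(full_design_combos(), key=lambda c: c[1] - c[0])
        d1 = np.array([c[0] for c in combos])
        d2 = np.array([c[1] for c in combos])
        for k in (0.2, 0.5, 0.9):
            phi = np.asarray(
                p_second_longer(1.0, d1, 1.0, d2, LeakParams("leaking", k))
            )
            # positive association of response probability with d2 - d1
            assert pearsonr(d2 - d1, phi)[0] > 0


class TestChiSquare:
    def test_perfect_fit_gives_zero(self):
        counts = counts_from_k(0.5, n_per=1000)
        phi = p_second_longer(
            1.0, counts.d1, 1.0, counts.d2, LeakParams("leaking", 0.5)
        )
        exact = ComboCounts(
            counts.d1, counts.d2, counts.n, np.round(counts.n * phi).astype(int)
        )
        fit = fit_k(exact, "leaking")
        chi2, df, p = chi_square_gof(exact, fit)
        assert chi2 < 1.0  # rounding of m leaves a trace; essentially 0
        assert p > 0.99

    def test_full_design_df_is_eleven(self):
        counts = counts_from_k(0.4, rng=np.random.default_rng(1))
        assert counts.n_combos == 12
        assert np.all(counts.n == 30)
        fit = fit_k(counts)
        assert fit.df == 11

    def test_low_expected_count_warns(self):
        counts = counts_from_k(0.9, n_per=2)
        fit = fit_k(counts)
        with pytest.warns(UserWarning, match="expected count"):
            chi_square_gof(counts, fit)
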