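"""Rate reconciliation, gross-error testing, Cochran-weighted summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from storflux.reconciliation import (MeasuredRates, cochran_weighted_stats,
                                     gross_error_test, reconcile_rates)


def two_species_carbon_balance(r1, r2, sd=1.0):
    """Two rates with one carbon balance: r1 + r2 = 0."""
    return MeasuredRates(
        species=["in", "out"], rates=np.array([r1, r2]),
        covariance=np.eye(2) * sd ** 2,
        composition=np.array([[1.0, 1.0]]), balances=("C",))


class TestReconcileRates:
    def test_balanced_rates_unchanged(self):
        m = two_species_carbon_balance(-3.0, 3.0)
        res = reconcile_rates(m)
        np.testing.assert_allclose(res.reconciled, m.rates, atol=1e-12)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_equal_variance_imbalance_split_evenly(self):
        """A single imbalance delta over two equal-variance rates is
        adjusted by delta/2 on each (hand projection)."""
        delta = 0.4
        m = two_species_carbon_balance(-3.0 + delta, 3.0)
        res = reconcile_rates(m)
        assert res.adjustments == pytest.approx([-delta / 2, -delta / 2])
        assert res.residual_after == pytest.approx([0.0], abs=1e-10)

    def test_idempotent(self):
        m = two_species_carbon_balance(-2.5, 3.1)
        once = reconcile_rates(m)
        m2 = MeasuredRates(species=m.species, rates=once.reconciled,
                           covariance=m.covariance,
                           composition=m.composition, balances=m.balances)
        twice = reconcile_rates(m2)
        np.testing.assert_allclose(twice.reconciled, once.reconciled,
                                   atol=1e-10)

    def test_reconciled_closer_to_truth_than_measured(self):
        """Monte-Carlo with known balanced truth: reconciliation reduces
        RMSE in at least 90 of 100 seeds."""
        truth = np.array([-4.0, 1.5, 2.5])
        E = np.array([[1.0, 1.0, 1.0]])
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 0.2, size=3)
            m = MeasuredRates(species=["s", "p", "q"], rates=noisy,
                              covariance=np.eye(3) * 0.04, composition=E,
                              balances=("C",))
            rec = reconcile_rates(m).reconciled
            if np.linalg.norm(rec - truth) <= np.linalg.norm(noisy - truth):
                wins += 1
        assert wins >= 90

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4),
           st.lists(st.floats(0.1, 2.0), min_size=4, max_size=4))
    def test_residual_zero_for_random_inputs(self, rates, sds):
        E = np.array([[1.0, 2.0, 1.0, 3.0], [0.0, 1.0, 1.0, 1.0]])
        m = MeasuredRates(species=list("abcd"), rates=np.array(rates),
                          covariance=np.diag(np.array(sds) ** 2),
                          composition=E, balances=("C", "N"))
        res = reconcile_rates(m)
        np.testing.assert_allclose(res.residual_after, 0.0, atol=1e-8)

    def test_covariance_must_be_positive_definite(self):
        with pytest.raises(ValueError, match="positive definite"):
            MeasuredRates(species=["a", "b"], rates=np.zeros(2),
                          covariance=np.zeros((2, 2)),
                          composition=np.ones((1, 2)))


class TestGrossErrorTest:
    def test_balanced_rates_give_h_zero_p_one(self):
        h, dof, p = gross_error_test(two_species_carbon_balance(-3.0, 3.0))
        assert h == pytest.approx(0.0, abs=1e-12)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_units_rescaling_invariance(self):
        m = two_species_carbon_balance(-3.0, 3.4, sd=0.3)
        h1, _, _ = gross_error_test(m)
        k = 1000.0  # e.g. mol -> mmol applied everywhere
        m2 = MeasuredRates(species=m.species, rates=m.rates * k,
                           covariance=m.covariance * k ** 2,
                           composition=m.composition, balances=("C",))
        h2, _, _ = gross_error_test(m2)
        assert h1 == pytest.approx(h2, rel=1e-10)

    def test_null_distribution_is_chi_square(self):
        """Empirical 95th percentile of h over 1e4 null draws within 10 %
        of the chi-square quantile."""
        from scipy import stats

        truth = np.array([-4.0, 1.5, 2.5, 0.7])
        E = np.array([[1.0, 1.0, 1.0, 1.0], [2.0, 0.0, 1.0, 0.5]])
        sd = 0.15
        rng = np.random.default_rng(42)
        # E @ truth is not zero; project truth onto the balance space first
        F = np.eye(4) * sd ** 2
        proj = F @ E.T @ np.linalg.solve(E @ F @ E.T, E @ truth)
        truth0 = truth - proj
        hs = np.empty(10_000)
        M = np.linalg.inv(E @ F @ E.T)
        for i in range(10_000):
            r = truth0 + rng.normal(0, sd, size=4)
            res = E @ r
            hs[i] = res @ M @ res
        emp95 = np.quantile(hs, 0.95)
        theo95 = stats.chi2.ppf(0.95, df=2)
        assert abs(emp95 - theo95) / theo95 < 0.10

    def test_corrupted_rate_detected_with_high_power(self):
        """+10 SD corruption on one rate: p < 0.01 in >= 95 of 100 seeds."""
        truth = np.array([-4.0, 1.5, 2.5])
        E = np.array([[1.0, 1.0, 1.0]])
        sd = 0.1
        detections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, sd, size=3)
            noisy[1] += 10 * sd
            m = MeasuredRates(species=["s", "p", "q"], rates=noisy,
                              covariance=np.eye(3) * sd ** 2, composition=E,
                              balances=("C",))
            _, _, p = gross_error_test(m)
            if p < 0.01:
                detections += 1
        assert detections >= 95


class TestCochranWeightedStats:
    def test_equal_errors_reduce_to_ordinary_mean_and_se(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10.0, 2.0, size=30)
        mean, se = cochran_weighted_stats(x, np.full(30, 0.5))
        assert mean == pytest.approx(float(np.mean(x)), rel=1e-12)
        assert se == pytest.approx(float(np.std(x, ddof=1) / np.sqrt(30)),
                                   rel=1e-9)

    def test_tiny_error_value_dominates_mean(self):
        mean, _ = cochran_weighted_stats([1.0, 100.0], [1e-9, 1.0])
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_formula_evaluation(self):
        """100 simulated solutions: spreadsheet-style re-evaluation of
        Cochran's formula."""
        rng = np.random.default_rng(3)
        x = rng.normal(5.0, 1.0, size=100)
        e = rng.uniform(0.2, 2.0, size=100)
        mean, se = cochran_weighted_stats(x, e)
        w = 1.0 / e
        n = len(x)
        xw = (w * x).sum() / w.sum()
        wbar = w.mean()
        t1 = ((w * x - wbar * xw) ** 2).sum()
        t2 = ((w - wbar) * (w * x - wbar * xw)).sum()
        t3 = ((w - wbar) ** 2).sum()
        var = n / ((n - 1) * w.sum() ** 2) * (t1 - 2 * xw * t2 + xw ** 2 * t3)
        assert mean == pytest.approx(xw, rel=1e-12)
        assert se == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            cochran_weighted_stats([1.0], [0.5])

    def test_nonpositive_errors_rejected(self):
        with pytest.raises(ValueError):
            cochran_weighted_stats([1.0, 2.0], [0.5, 0.0])
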