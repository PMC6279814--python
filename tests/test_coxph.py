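"""Cox engine: oracle equivalence, baseline hazard, chi-square, guards."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, NelsonAalenFitter

from dynapred.coxph import (
    breslow_baseline,
    cox_partial_loglik,
    fit_cox,
    model_chi_square,
)
from dynapred.exceptions import DomainError, EstimationError

from conftest import exponential_cohort


def brute_force_pl(beta, x, time, status, entry=None):
    """Hand-written Breslow partial log-likelihood, one covariate."""
    entry = np.zeros_like(time) if entry is None else entry
    ll = 0.0
    for t in np.unique(time[status == 1]):
        events = (time == t) & (status == 1)
        risk = (entry < t) & (time >= t)
        ll += beta * x[events].sum() - events.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestFitCox:
    def test_identical_groups_coefficient_zero(self):
        # two copies of the same survival experience across groups
        time = np.array([1.0, 2, 3, 1, 2, 3])
        status = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        fit = fit_cox(x, time, status)
        assert abs(fit.coefficients.iloc[0]) < 1e-8

    def test_matches_brute_force_grid_four_subjects(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        time = np.array([1.0, 3.0, 2.0, 4.0])
        status = np.ones(4, dtype=int)
        fit = fit_cox(x, time, status)
        grid = np.arange(-3, 3, 1e-4)
        lls = [brute_force_pl(b, x, time, status) for b in grid]
        assert abs(fit.coefficients.iloc[0] - grid[int(np.argmax(lls))]) < 1e-4

    def test_matches_brute_force_grid_with_delayed_entry(self):
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        entry = np.array([0.0, 0.0, 1.0, 2.0, 2.5])
        time = np.array([2.0, 1.5, 3.0, 4.0, 3.5])
        status = np.array([1, 1, 1, 0, 1])
        fit = fit_cox(x, time, status, entry=entry)
        grid = np.arange(-4, 4, 1e-4)
        lls = [brute_force_pl(b, x, time, status, entry) for b in grid]
        assert abs(fit.coefficients.iloc[0] - grid[int(np.argmax(lls))]) < 1e-4

    def test_matches_lifelines_with_delayed_entry(self):
        # continuous times (no ties), so Efron and Breslow coincide
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=(n, 2))
        T = rng.exponential(np.exp(-(0.6 * x[:, 0] - 0.3 * x[:, 1])))
        C = rng.exponential(1.0, n)
        time, status = np.minimum(T, C), (T <= C).astype(int)
        entry = rng.uniform(0, time * 0.4)
        fit = fit_cox(x, time, status, entry=entry)
        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "T": time, "E": status, "s": entry})
        ll = CoxPHFitter().fit(df, "T", "E", entry_col="s")
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ll.params_.to_numpy(), atol=2e-4)
        assert abs(fit.loglik_full - ll.log_likelihood_) < 1e-4

    def test_matches_sksurv_breslow_with_ties(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        rng = np.random.default_rng(8)
        n = 150
        x = rng.normal(size=(n, 2))
        T = np.round(rng.exponential(np.exp(-(0.6 * x[:, 0] - 0.3 * x[:, 1]))), 1) + 0.1
        C = rng.exponential(1.0, n)
        time, status = np.minimum(T, C), (T <= C).astype(int)
        fit = fit_cox(x, time, status)
        ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-10).fit(
            x, Surv.from_arrays(status.astype(bool), time))
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.coef_, atol=2e-5)

    def test_recovers_simulation_truth(self):
        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x, time, status = exponential_cohort(rng, 500, beta=0.7, censor_scale=1.5)
            estimates.append(fit_cox(x, time, status).coefficients.iloc[0])
        assert abs(np.mean(estimates) - 0.7) < 0.1

    def test_case_weights_equal_replication(self):
        rng = np.random.default_rng(5)
        x, time, status = exponential_cohort(rng, 40, beta=0.5, censor_scale=2.0)
        w = rng.integers(1, 4, size=40)
        fit_w = fit_cox(x, time, status, weights=w.astype(float))
        rep = np.repeat(np.arange(40), w)
        fit_r = fit_cox(x[rep], time[rep], status[rep])
        np.testing.assert_allclose(fit_w.coefficients.to_numpy(),
                                   fit_r.coefficients.to_numpy(), atol=1e-6)

    def test_loglik_full_never_below_null(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            x, time, status = exponential_cohort(np.random.default_rng(seed), 60,
                                                 beta=0.0, censor_scale=2.0)
            fit = fit_cox(x, time, status)
            assert fit.loglik_full >= fit.loglik_null - 1e-10

    def test_separation_raises_with_covariate_name(self):
        # perfectly ordered covariate: monotone likelihood
        time = np.arange(1.0, 9.0)
        status = np.ones(8, dtype=int)
        x = pd.DataFrame({"marker": np.arange(8.0)})
        with pytest.raises(EstimationError, match="marker"):
            fit_cox(x, time, status)

    def test_input_guards(self):
        with pytest.raises(EstimationError, match="constant"):
            fit_cox(np.ones((5, 1)), np.arange(1.0, 6), np.array([1, 0, 1, 0, 1]))
        with pytest.raises(DomainError):
            fit_cox(np.random.randn(3, 1), np.array([1.0, 2, 3]), np.array([1, 1, 1]),
                    entry=np.array([0.0, 2.5, 0.0]))
        with pytest.raises(EstimationError, match="no events"):
            fit_cox(np.random.randn(4, 1), np.arange(1.0, 5), np.zeros(4, dtype=int))


class TestBreslowBaseline:
    def test_null_model_equals_nelson_aalen(self):
        rng = np.random.default_rng(2)
        _, time, status = exponential_cohort(rng, 150, censor_scale=1.0)
        fit = fit_cox(np.empty((150, 0)), time, status)
        na = NelsonAalenFitter().fit(time, status)
        ts = np.quantile(time, [0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(fit.baseline_cumhaz(ts),
                                   na.cumulative_hazard_at_times(ts).to_numpy(), atol=1e-10)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(7)
        time = rng.exponential(2.0, size=1000)  # rate 0.5
        status = np.ones(1000, dtype=int)
        fit = fit_cox(np.empty((1000, 0)), time, status)
        grid = np.linspace(0.05, 2.0, 100)
        assert np.max(np.abs(fit.baseline_cumhaz(grid) - 0.5 * grid)) < 0.1

    def test_three_subject_hand_increments(self):
        # events at 1 and 2 (subject 3 censored at 3), beta fixed at 0
        x = np.array([0.0, 1.0, 0.5])
        time = np.array([1.0, 2.0, 3.0])
        status = np.array([1, 1, 0])
        fit = fit_cox(np.empty((3, 0)), time, status)
        H = breslow_baseline(fit, np.empty((3, 0)), time, status)
        np.testing.assert_allclose(H(np.array([1.0, 2.0, 5.0])),
                                   [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2])

    def test_predicted_survival_valid_and_monotone(self):
        rng = np.random.default_rng(13)
        x, time, status = exponential_cohort(rng, 100, beta=0.8, censor_scale=1.0)
        fit = fit_cox(x, time, status)
        grid = np.linspace(0.01, time.max(), 50)
        S = fit.predict_survival(x[:, None], grid)
        assert np.all((S >= 0) & (S <= 1))
        assert np.all(np.diff(S, axis=1) <= 1e-12)


class TestModelChiSquare:
    def test_zero_coefficient_fit_gives_zero(self):
        time = np.array([1.0, 2, 3, 1, 2, 3])
        status = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        stat, df, p = model_chi_square(fit_cox(x, time, status))
        assert stat < 1e-8 and df == 1 and p > 0.999

    def test_null_data_mean_approximates_df(self):
        # LR statistic is asymptotically chi-square(1) under the null
        stats = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            x, time, status = exponential_cohort(rng, 40, beta=0.0, censor_scale=2.0)
            stats.append(model_chi_square(fit_cox(x, time, status))[0])
        assert abs(np.mean(stats) - 1.0) < 0.35

    def test_additive_across_nesting(self):
        rng = np.random.default_rng(21)
        n = 150
        X = rng.normal(size=(n, 2))
        T = rng.exponential(np.exp(-(0.5 * X[:, 0] + 0.5 * X[:, 1])))
        status = np.ones(n, dtype=int)
        full = fit_cox(X, T, status)
        sub = fit_cox(X[:, :1], T, status)
        lr_full, _, _ = model_chi_square(full)
        lr_sub, _, _ = model_chi_square(sub)
        lr_step = 2 * (full.loglik_full - sub.loglik_full)
        np.testing.assert_allclose(lr_full, lr_sub + lr_step, atol=1e-8)


def test_partial_loglik_matches_brute_force():
    rng = np.random.default_rng(4)
    x, time, status = exponential_cohort(rng, 30, beta=0.4, censor_scale=1.5)
    for b in (-0.5, 0.0, 0.8):
        np.testing.assert_allclose(
            cox_partial_loglik(np.array([b]), x, time, status),
            brute_force_pl(b, x, time, status), atol=1e-10)
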