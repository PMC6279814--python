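"""Landmark stacking, the pooled (ipl*) supermodel, and window mortality."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dynapred._stepfun import StepFunction
from dynapred.coxph import fit_cox
from dynapred.datasets import SurvivalDataset
from dynapred.exceptions import ConfigurationError, DomainError
from dynapred.landmark import (
    LandmarkConfig,
    SupermodelFit,
    build_landmark_stack,
    dynamic_window_mortality,
    evaluate_effect,
    fit_supermodel_ipl_star,
    mortality_curves,
)
from dynapred.simulate import ClinicalVar, SimConfig, simulate_cohort


def _dataset(times, statuses):
    ids = [f"S{i}" for i in range(len(times))]
    data = pd.DataFrame({"time": times, "status": statuses},
                        index=pd.Index(ids, name="subject_id"))
    return SurvivalDataset(data), pd.Series(np.zeros(len(times)), index=ids)


def stacked_partial_loglik(beta, X, entry, exit_, status):
    """Independent implementation of the stacked delayed-entry Breslow
    partial likelihood (test oracle)."""
    eta = X @ beta
    ll = 0.0
    for tt in np.unique(exit_[status == 1]):
        events = (exit_ == tt) & (status == 1)
        risk = (entry < tt) & (exit_ >= tt)
        ll += eta[events].sum() - events.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


class TestStackConstruction:
    def test_censored_subject_enumeration(self):
        ds, cvpi = _dataset([10.0], [0])
        stack = build_landmark_stack(ds, cvpi, LandmarkConfig(s_grid=np.array([0.0, 1.0, 2.0]), w=5.0, tau=7.0))
        assert len(stack) == 3
        np.testing.assert_allclose(stack["exit"], [5.0, 6.0, 7.0])
        assert (stack["status_w"] == 0).all()
        np.testing.assert_allclose(stack["entry"], [0.0, 1.0, 2.0])

    def test_event_inside_every_window(self):
        ds, cvpi = _dataset([3.0], [1])
        stack = build_landmark_stack(ds, cvpi, LandmarkConfig(s_grid=np.array([0.0, 1.0, 2.0]), w=5.0, tau=7.0))
        assert len(stack) == 3
        np.testing.assert_allclose(stack["exit"], [3.0, 3.0, 3.0])
        assert (stack["status_w"] == 1).all()

    def test_subject_leaves_after_failure(self):
        ds, cvpi = _dataset([1.5], [1])
        stack = build_landmark_stack(ds, cvpi, LandmarkConfig(s_grid=np.array([0.0, 1.0, 2.0]), w=5.0, tau=7.0))
        assert list(stack["s"]) == [0.0, 1.0]  # not at risk at s=2

    def test_record_count_matches_direct_at_risk_sum(self, default_cohort):
        config = LandmarkConfig()
        cvpi = pd.Series(np.zeros(default_cohort.n_subjects), index=default_cohort.subject_id)
        stack = build_landmark_stack(default_cohort, cvpi, config)
        expected = sum(int((default_cohort.time > s).sum()) for s in config.s_grid)
        assert len(stack) == expected

    def test_every_at_risk_pair_appears_exactly_once(self):
        ds, _ = _dataset([0.5, 2.0, 4.0, 9.0], [1, 0, 1, 0])
        cvpi = pd.Series(np.zeros(4), index=ds.subject_id)
        config = LandmarkConfig(s_grid=np.array([0.0, 1.0, 3.0]), w=5.0, tau=7.0)
        stack = build_landmark_stack(ds, cvpi, config)
        pairs = set(zip(stack["subject_id"], stack["s"]))
        expected = {(i, s) for s in config.s_grid for i, t in zip(ds.subject_id, ds.time) if t > s}
        assert pairs == expected and len(stack) == len(expected)

    def test_basis_columns(self):
        ds, _ = _dataset([6.0], [0])
        cvpi = pd.Series([2.0], index=ds.subject_id)
        stack = build_landmark_stack(ds, cvpi, LandmarkConfig(s_grid=np.array([0.0, 3.5]), w=5.0, tau=7.0))
        np.testing.assert_allclose(stack["s_tau"], [0.0, 0.5])
        np.testing.assert_allclose(stack["s_tau_sq"], [0.0, 0.25])
        np.testing.assert_allclose(stack["x_s_tau"], [0.0, 1.0])

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            LandmarkConfig(s_grid=np.array([0.0, 1.0]), w=-1.0, tau=7.0).validate()
        with pytest.raises(ConfigurationError):
            LandmarkConfig(s_grid=np.array([0.0, 9.0]), w=5.0, tau=7.0).validate()


class TestSupermodelFit:
    def _small_stack(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-0.8 * x)) * 3
        C = rng.exponential(5.0, n)
        t, s = np.minimum(T, C), (T <= C).astype(int)
        ids = [f"S{i}" for i in range(n)]
        data = pd.DataFrame({"time": t, "status": s}, index=pd.Index(ids, name="subject_id"))
        ds = SurvivalDataset(data)
        config = LandmarkConfig(s_grid=np.array([0.0, 1.0, 2.0]), w=3.0, tau=7.0)
        return build_landmark_stack(ds, pd.Series(x, index=ids), config), config

    def test_matches_independent_optimizer(self):
        stack, config = self._small_stack()
        fit = fit_supermodel_ipl_star(stack, config, robust_se=False)
        X = stack[["s_tau", "s_tau_sq", "x", "x_s_tau"]].to_numpy()
        args = (X, stack["entry"].to_numpy(), stack["exit"].to_numpy(),
                stack["status_w"].to_numpy())
        res = optimize.minimize(lambda b: -stacked_partial_loglik(b, *args),
                                np.zeros(4), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000})
        got = fit.cox_fit.coefficients.to_numpy()
        np.testing.assert_allclose(got, res.x, atol=1e-3)

    def test_single_covariate_grid_oracle_on_tiny_stack(self):
        # <=10 records, x-only model, delayed entry: 1-d grid maximization
        entry = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        exit_ = np.array([1.5, 2.5, 4.0, 2.5, 3.0, 4.5])
        status = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, -1.0, 1.0, 0.0, -1.0])
        fit = fit_cox(x, exit_, status, entry=entry)
        grid = np.arange(-3, 3, 1e-4)
        lls = [stacked_partial_loglik(np.array([b]), x[:, None], entry, exit_, status)
               for b in grid]
        assert abs(fit.coefficients.iloc[0] - grid[int(np.argmax(lls))]) < 1e-3

    def test_robust_se_attached(self):
        stack, config = self._small_stack()
        fit = fit_supermodel_ipl_star(stack, config, robust_se=True)
        assert fit.robust_covariance.shape == (4, 4)
        assert np.all(np.diag(fit.robust_covariance) > 0)

    def test_positive_tv_slope_gives_positive_interaction(self):
        agree = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = SimConfig(n_subjects=300, n_genes=1, n_causal_genes=0, gene_effect_sizes=(),
                            clinical_spec=[ClinicalVar("z", "continuous", 0.8)],
                            tv_slope=0.4, seed=seed)
            ds = simulate_cohort(cfg)
            x = ds.truth.linear_predictor
            config = LandmarkConfig(s_grid=np.round(np.arange(0.0, 7.01, 0.5), 10), w=5.0, tau=7.0)
            stack = build_landmark_stack(ds, x, config)
            fit = fit_supermodel_ipl_star(stack, config, robust_se=False)
            agree += fit.beta1 > 0
        assert agree >= 9


class TestEffectAndMortality:
    def _manual_fit(self, g1=0.4, g2=-0.2, b0=1.0, b1=-0.5, knots=None, values=None):
        config = LandmarkConfig(s_grid=np.round(np.arange(0.0, 7.01, 0.1), 10), w=5.0, tau=7.0)
        if knots is None:
            knots = np.linspace(0.2, 12.0, 60)
            values = 0.05 * knots  # constant hazard 0.05
        return SupermodelFit(gamma1=g1, gamma2=g2, beta0=b0, beta1=b1,
                             baseline_cumhaz=StepFunction(knots, values),
                             config=config, cox_fit=None)

    def test_effect_at_zero_and_tau(self):
        fit = self._manual_fit()
        assert evaluate_effect(fit, 0.0) == (0.0, 1.0)
        base, eff = evaluate_effect(fit, 7.0)
        np.testing.assert_allclose([base, eff], [0.4 - 0.2, 1.0 - 0.5])

    def test_effect_midpoint_arithmetic(self):
        fit = self._manual_fit()
        base, eff = evaluate_effect(fit, 3.5)
        np.testing.assert_allclose([base, eff], [0.4 * 0.5 - 0.2 * 0.25, 1.0 - 0.5 * 0.5])

    def test_effect_domain_error(self):
        with pytest.raises(DomainError):
            evaluate_effect(self._manual_fit(), 7.5)

    def test_no_events_in_window_gives_zero(self):
        # H0 flat on [2, 9]: the window [3, 8] has no hazard increments
        fit = self._manual_fit(knots=np.array([1.0, 2.0, 9.0]),
                               values=np.array([0.3, 0.5, 0.5]))
        fit.gamma1 = fit.gamma2 = fit.beta1 = 0.0
        assert dynamic_window_mortality(fit, 1.0, 3.0) == 0.0

    def test_null_supermodel_exponential_closed_form(self):
        # zero coefficients, H0 from a null Cox fit on exponential data
        rng = np.random.default_rng(5)
        lam, w = 0.4, 2.0
        t = rng.exponential(1 / lam, 1000)
        fit0 = fit_cox(np.empty((1000, 0)), t, np.ones(1000, dtype=int))
        config = LandmarkConfig(s_grid=np.array([0.0, 0.5, 1.0]), w=w, tau=7.0)
        sm = SupermodelFit(0.0, 0.0, 0.0, 0.0, fit0.baseline_cumhaz, config, None)
        expected = 1.0 - np.exp(-lam * w)
        for s in (0.0, 0.5, 1.0):
            assert abs(dynamic_window_mortality(sm, 0.0, s) - expected) < 0.05

    def test_monotone_in_index_when_effect_positive(self):
        fit = self._manual_fit(b0=1.0, b1=-0.5)  # effect stays positive on [0, tau]
        for s in (0.0, 2.0, 5.0):
            vals = [dynamic_window_mortality(fit, x, s) for x in (-1.0, 0.0, 1.0)]
            assert vals[0] < vals[1] < vals[2]

    def test_curves_equal_for_equal_index(self):
        fit = self._manual_fit()
        prof = pd.DataFrame({"cvpi_comb": [0.7, 0.7]}, index=["P1", "P2"])
        curves = mortality_curves(fit, prof)
        a = curves[curves["profile"] == "P1"]["mortality"].to_numpy()
        b = curves[curves["profile"] == "P2"]["mortality"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_high_profile_dominates_low(self):
        fit = self._manual_fit(b0=1.2, b1=-0.5)
        prof = pd.DataFrame({"cvpi_comb": [-0.8, 0.8]}, index=["A", "D"])
        curves = mortality_curves(fit, prof)
        a = curves[curves["profile"] == "A"]["mortality"].to_numpy()
        d = curves[curves["profile"] == "D"]["mortality"].to_numpy()
        assert np.all(d >= a)

    def test_location_invariance_after_refit(self):
        # adding a constant to the index and refitting leaves mortality unchanged
        rng = np.random.default_rng(9)
        n = 150
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-0.7 * x)) * 4
        C = rng.exponential(8.0, n)
        t, s = np.minimum(T, C), (T <= C).astype(int)
        ids = [f"S{i}" for i in range(n)]
        data = pd.DataFrame({"time": t, "status": s}, index=pd.Index(ids, name="subject_id"))
        ds = SurvivalDataset(data)
        config = LandmarkConfig(s_grid=np.round(np.arange(0.0, 3.01, 0.5), 10), w=3.0, tau=7.0)
        fits = []
        for shift in (0.0, 2.5):
            stack = build_landmark_stack(ds, pd.Series(x + shift, index=ids), config)
            fits.append(fit_supermodel_ipl_star(stack, config, robust_se=False))
        m0 = [dynamic_window_mortality(fits[0], xi, 1.0) for xi in (-1.0, 0.5)]
        m1 = [dynamic_window_mortality(fits[1], xi + 2.5, 1.0) for xi in (-1.0, 0.5)]
        np.testing.assert_allclose(m0, m1, atol=1e-6)
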