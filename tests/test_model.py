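"""Logistic NTCP fitting: likelihood, MLE, re-parameterization, bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special

from presbydose import SimulationConfig, TrueCoefficients, simulate_cohort

from .conftest import grid_search_logistic
from presbydose.model import (
    BootstrapEnsemble,
    ConvergenceError,
    DegenerateOutcomeError,
    NonMonotoneResponseError,
    NTCPModel,
    NTCPResults,
    SeparationError,
    bootstrap,
    derive_d50_gamma,
    fit_mle,
    negative_log_likelihood,
    ntcp_probability,
)


def results_with(params, roi="MGM", covariates=("age",), n=50):
    """A results object with prescribed coefficients on a dummy cohort."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "dose_MGM": rng.uniform(20, 70, n),
        "age": rng.uniform(40, 80, n),
        "outcome": rng.integers(0, 2, n),
    })
    model = NTCPModel(df, roi, list(covariates))
    p = np.asarray(params, float)
    return NTCPResults(model=model, params=p, cov=np.eye(len(p)), llf=0.0)


class TestNtcpProbability:
    def test_logistic_midpoint(self):
        fit = results_with([-4.0, 0.08], covariates=())
        assert ntcp_probability(fit, 50.0) == pytest.approx(0.5, abs=1e-12)

    def test_known_linear_predictor(self):
        # lp = -5 + 0.08*50 + 0.04*70 = 1.8
        fit = results_with([-5.0, 0.08, 0.04])
        p = ntcp_probability(fit, 50.0, {"age": 70.0})
        assert p == pytest.approx(1 / (1 + np.exp(-1.8)), abs=1e-12)
        assert p == pytest.approx(0.8581, abs=1e-4)

    def test_strictly_increasing_in_dose(self):
        fit = results_with([-5.0, 0.08, 0.04])
        doses = np.linspace(0, 80, 41)
        probs = ntcp_probability(fit, doses, {"age": 60.0})
        assert np.all(np.diff(probs) > 0)

    def test_missing_covariate_errors(self):
        fit = results_with([-5.0, 0.08, 0.04])
        with pytest.raises(KeyError):
            ntcp_probability(fit, 50.0, {})


class TestNegativeLogLikelihood:
    def test_all_half_probabilities(self):
        cohort = simulate_cohort(SimulationConfig(n=300, seed=3))
        nll = negative_log_likelihood([0.0, 0.0], cohort, "MGM")
        assert nll == pytest.approx(300 * np.log(2), abs=1e-9)

    def test_near_perfect_prediction_approaches_zero(self):
        df = pd.DataFrame({"dose_MGM": [10.0, 90.0] * 10, "outcome": [0, 1] * 10})
        nll = negative_log_likelihood([-50.0, 1.0], df, "MGM")
        assert nll < 1e-8

    def test_null_model_on_reference_counts(self, counts_cohort):
        # 34 events / 266 non-events at the event-fraction intercept
        phat = 34 / 300
        nll = negative_log_likelihood(
            [special.logit(phat)], counts_cohort, "any", include_dose=False
        )
        expected = -(34 * np.log(phat) + 266 * np.log(1 - phat))
        assert nll == pytest.approx(expected, abs=1e-9)
        assert nll == pytest.approx(106.03, abs=0.01)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood([0.0], pd.DataFrame({"outcome": []}), "x",
                                    include_dose=False)


class TestFitMLE:
    def test_intercept_only_is_logit_of_event_fraction(self, counts_cohort):
        res = fit_mle(counts_cohort, "any", include_dose=False)
        assert res.params["intercept"] == pytest.approx(special.logit(34 / 300), abs=1e-8)

    def test_matches_brute_force_grid_on_toy_cohort(self):
        rng = np.random.default_rng(42)
        doses = rng.uniform(20, 70, 20)
        p = special.expit(-5 + 0.09 * doses)
        outcome = (rng.random(20) < p).astype(int)
        df = pd.DataFrame({"dose_MGM": doses, "outcome": outcome})
        res = fit_mle(df, "MGM")

        b0, bd, b0_step, bd_step = grid_search_logistic(doses, outcome)
        assert res.params["intercept"] == pytest.approx(b0, abs=2 * b0_step)
        assert res.params["dose"] == pytest.approx(bd, abs=2 * bd_step)

    def test_agrees_with_statsmodels(self, cohort3000, mgm_fit):
        X = sm.add_constant(cohort3000[["dose_MGM", "age"]])
        ref = sm.Logit(cohort3000["outcome"], X).fit(disp=0, tol=1e-12)
        assert np.allclose(mgm_fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
        assert mgm_fit.llf == pytest.approx(ref.llf, abs=1e-8)
        assert np.allclose(mgm_fit.bse.to_numpy(), ref.bse.to_numpy(), rtol=1e-4)

    def test_gradient_vanishes_at_mle(self, mgm_fit):
        g = mgm_fit.model.score(mgm_fit.params.to_numpy())
        assert np.max(np.abs(g)) < 1e-6

    def test_parameter_recovery_within_3se(self):
        truth = TrueCoefficients()
        cohort = simulate_cohort(SimulationConfig(n=3000, seed=17))
        res = fit_mle(cohort, "MGM", ["age"])
        true_vec = np.array([truth.beta0, truth.beta_dose, truth.beta_age])
        z = np.abs((res.params.to_numpy() - true_vec) / res.bse.to_numpy())
        assert np.all(z < 3)

    def test_forced_separation_raises(self):
        doses = np.linspace(10, 80, 40)
        df = pd.DataFrame({"dose_MGM": doses, "outcome": (doses > 60).astype(int)})
        with pytest.raises(SeparationError):
            fit_mle(df, "MGM")

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"dose_MGM": [10.0, 20.0, 30.0], "outcome": [0, 0, 0]})
        with pytest.raises(DegenerateOutcomeError):
            fit_mle(df, "MGM")

    def test_deviance_nesting(self, cohort300):
        null = fit_mle(cohort300, "MGM", include_dose=False)
        dose_only = fit_mle(cohort300, "MGM")
        full = fit_mle(cohort300, "MGM", ["age", "sex_male"])
        assert full.deviance <= dose_only.deviance + 1e-9
        assert dose_only.deviance <= null.deviance + 1e-9

    def test_bic_identity(self, mgm_fit):
        assert mgm_fit.bic == pytest.approx(
            3 * np.log(mgm_fit.n) - 2 * mgm_fit.llf, abs=1e-10
        )

    def test_summary_mentions_all_coefficients(self, mgm_fit):
        text = mgm_fit.summary()
        for name in ("intercept", "dose", "age", "BIC", "AUC"):
            assert name in text

    def test_serialization_round_trip(self, mgm_fit):
        import json

        d = json.loads(mgm_fit.to_json())
        assert d["roi"] == "MGM"
        assert np.allclose(d["coefficients"], mgm_fit.params.to_numpy())
        assert d["n"] == 3000


class TestD50Gamma:
    def test_closed_form(self):
        fit = results_with([-6.0, 0.1], covariates=())
        dr = derive_d50_gamma(fit)
        assert dr.d50 == pytest.approx(60.0, abs=1e-12)
        assert dr.gamma50 == pytest.approx(1.5, abs=1e-12)

    def test_probability_at_d50_is_half(self, mgm_fit):
        dr = mgm_fit.d50_gamma({"age": 65.0})
        assert ntcp_probability(mgm_fit, dr.d50, {"age": 65.0}) == pytest.approx(0.5, abs=1e-9)

    def test_slope_at_d50_by_finite_differences(self, mgm_fit):
        profile = {"age": 65.0}
        dr = mgm_fit.d50_gamma(profile)
        h = 1e-5
        slope = (
            ntcp_probability(mgm_fit, dr.d50 + h, profile)
            - ntcp_probability(mgm_fit, dr.d50 - h, profile)
        ) / (2 * h)
        assert slope == pytest.approx(mgm_fit.beta_dose / 4, abs=1e-6)

    def test_nonpositive_dose_slope_rejected(self):
        fit = results_with([-6.0, -0.1], covariates=())
        with pytest.raises(NonMonotoneResponseError):
            derive_d50_gamma(fit)


class TestBootstrap:
    def test_seeded_reproducibility(self, cohort300):
        e1 = bootstrap(cohort300, "MGM", ["age"], B=25, seed=9)
        e2 = bootstrap(cohort300, "MGM", ["age"], B=25, seed=9)
        assert np.array_equal(e1.params, e2.params, equal_nan=True)
        assert np.array_equal(e1.converged, e2.converged)

    def test_different_seeds_differ(self, cohort300):
        e1 = bootstrap(cohort300, "MGM", ["age"], B=10, seed=1)
        e2 = bootstrap(cohort300, "MGM", ["age"], B=10, seed=2)
        assert not np.array_equal(e1.params, e2.params, equal_nan=True)

    def test_replicates_match_direct_refits(self, cohort300):
        """Each replicate's coefficients equal a direct fit on its resample."""
        B, seed = 5, 13
        ens = bootstrap(cohort300, "MGM", ["age"], B=B, seed=seed)
        rng = np.random.default_rng(seed)
        for b in range(B):
            idx = rng.integers(0, len(cohort300), size=len(cohort300))
            direct = fit_mle(cohort300.iloc[idx], "MGM", ["age"])
            assert np.allclose(ens.params[b], direct.params.to_numpy(), atol=1e-8)

    def test_interval_and_band_shapes(self, cohort300):
        ens = bootstrap(cohort300, "MGM", ["age"], B=40, seed=3)
        lo, hi = ens.coefficient_interval("dose")
        assert lo < hi
        band = ens.predict_band(np.array([20.0, 40.0, 60.0]), {"age": 65.0})
        assert list(band.columns) == ["dose", "lower", "upper"]
        assert np.all(band["lower"] <= band["upper"])

    def test_majority_failure_raises(self):
        params = np.full((4, 2), np.nan)
        params[0] = [0.0, 0.1]
        with pytest.raises(ConvergenceError):
            BootstrapEnsemble(seed=0, B=4, param_names=["intercept", "dose"],
                              params=params,
                              converged=np.array([True, False, False, False]))

    def test_coverage_of_generating_slope(self):
        """Percentile intervals for the dose slope cover the truth at
        roughly nominal rate over simulated cohorts."""
        truth = TrueCoefficients()
        hits = 0
        n_sims = 25
        for s in range(n_sims):
            cohort = simulate_cohort(SimulationConfig(n=1000, seed=100 + s))
            ens = bootstrap(cohort, "MGM", ["age"], B=199, seed=500 + s)
            lo, hi = ens.coefficient_interval("dose")
            hits += lo <= truth.beta_dose <= hi
        assert hits >= 21  # >= ~85% observed coverage for a 95% interval
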