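"""BIC stepwise selection, FDR adjustment, AUC, diagnostics table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presbydose import SimulationConfig, TrueCoefficients, simulate_cohort
from presbydose.model import fit_mle
from presbydose.selection import (
    benjamini_hochberg,
    bic_score,
    diagnostics_table,
    forward_stepwise,
    roc_auc,
)


def bh_brute_force(pvals):
    """Step-up BH by direct enumeration of the rank rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def auc_brute_force(scores, outcomes):
    """Mann–Whitney pair counting with half-weight ties."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestBicScore:
    def test_closed_form_unit_case(self):
        assert bic_score(0.0, 1, np.e) == pytest.approx(1.0)
        # adding a parameter with no likelihood gain costs exactly ln(n)
        assert bic_score(-5.0, 3, 100) - bic_score(-5.0, 2, 100) == pytest.approx(np.log(100))

    def test_null_model_on_reference_counts(self, counts_cohort):
        res = fit_mle(counts_cohort, "any", include_dose=False)
        assert bic_score(res.llf, 1, 300) == pytest.approx(res.bic, abs=1e-10)
        assert res.bic == pytest.approx(np.log(300) + 2 * 106.035, abs=0.02)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            bic_score(0.0, 0, 10)
        with pytest.raises(ValueError):
            bic_score(0.0, 1, 0)


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_three_value_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_equal_ps_unchanged(self):
        adj = benjamini_hochberg([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force_and_dominates_raw(self, pvals):
        adj = benjamini_hochberg(pvals)
        assert np.allclose(adj, bh_brute_force(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = benjamini_hochberg(pvals)
        adj_perm = benjamini_hochberg([pvals[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm, atol=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_partial_ordering_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30),
           st.integers(min_value=0, max_value=2**20))
    def test_matches_brute_force(self, scores, seed):
        rng = np.random.default_rng(seed)
        outcomes = rng.integers(0, 2, len(scores))
        if len(np.unique(outcomes)) < 2:
            outcomes[0], outcomes[-1] = 0, 1
        assert roc_auc(scores, outcomes) == pytest.approx(
            auc_brute_force(scores, outcomes), abs=1e-12
        )

    def test_complement_and_monotone_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)  # ties almost surely absent
        outcomes = rng.integers(0, 2, 40)
        outcomes[:2] = [0, 1]
        a = roc_auc(scores, outcomes)
        assert a + roc_auc(-scores, outcomes) == pytest.approx(1.0)
        assert roc_auc(np.exp(scores), outcomes) == pytest.approx(a)


class TestForwardStepwise:
    def test_selects_age_when_age_drives_outcome(self):
        cohort = simulate_cohort(SimulationConfig(
            n=3000, seed=31,
            true_coefficients=TrueCoefficients(beta0=-9.0, beta_dose=0.06, beta_age=0.08),
        ))
        res = forward_stepwise(
            cohort, "MGM", ["sex_male", "t34", "age", "smoking", "chemo_cisplatin"]
        )
        assert res.selected[:1] == ["age"]
        assert all(b2 < b1 for b1, b2 in zip(res.bic_trace, res.bic_trace[1:]))

    def test_pure_noise_candidates_mostly_rejected(self):
        kept = 0
        for seed in range(20):
            cohort = simulate_cohort(SimulationConfig(
                n=1000, seed=600 + seed,
                true_coefficients=TrueCoefficients(beta0=-2.1, beta_dose=0.0, beta_age=0.0),
            ))
            res = forward_stepwise(
                cohort, "MGM", ["sex_male", "t34", "n2b3", "smoking", "chemo_cisplatin"]
            )
            kept += len(res.selected) == 0
        assert kept >= 15

    def test_duplicated_candidate_tie_broken_by_order(self, cohort300):
        cohort = cohort300.copy()
        cohort["age_copy"] = cohort["age"]
        res = forward_stepwise(cohort, "MGM", ["age_copy", "age"])
        assert res.selected[0] == "age_copy"

    def test_deterministic_given_inputs(self, cohort300):
        r1 = forward_stepwise(cohort300, "MGM", ["age", "sex_male", "t34"])
        r2 = forward_stepwise(cohort300, "MGM", ["age", "sex_male", "t34"])
        assert r1.selected == r2.selected
        assert r1.bic_trace == r2.bic_trace

    def test_failing_candidate_excluded_with_warning(self, cohort300):
        cohort = cohort300.copy()
        # a candidate that forces separation: equals the outcome itself
        cohort["leak"] = cohort["outcome"] * 1000.0
        with pytest.warns(RuntimeWarning, match="leak"):
            res = forward_stepwise(cohort, "MGM", ["leak", "age"])
        assert "leak" not in res.selected

    def test_empty_candidates_rejected(self, cohort300):
        with pytest.raises(ValueError):
            forward_stepwise(cohort300, "MGM", [])


class TestDiagnosticsTable:
    @pytest.fixture(scope="class")
    def eight_fits(self):
        fits = {}
        for i, roi in enumerate(
            ("ADM", "GGM", "IPC", "ITM", "MGM", "MPC", "PDM", "SPC")
        ):
            # only MGM (the driver) has a real dose effect in the generator
            cohort = simulate_cohort(SimulationConfig(n=800, seed=900 + i))
            fits[roi] = fit_mle(cohort, roi, ["age"])
        return fits

    def test_strong_dose_effect_has_smallest_adjusted_p(self, eight_fits):
        table = diagnostics_table(eight_fits)
        row = table.loc[table["muscle"] == "MGM"].iloc[0]
        assert row["dose_fdr_p"] == table["dose_fdr_p"].min()

    def test_adjusted_dominates_raw(self, eight_fits):
        table = diagnostics_table(eight_fits)
        assert np.all(table["dose_fdr_p"] >= table["dose_p_raw"] - 1e-12)
        assert np.all(table["age_fdr_p"] >= table["age_p_raw"] - 1e-12)

    def test_identical_fits_give_identical_rows(self, cohort300):
        fit = fit_mle(cohort300, "MGM", ["age"])
        table = diagnostics_table([fit, fit, fit])
        cols = ["dose_fdr_p", "age_fdr_p", "bic", "auc"]
        assert (table[cols].nunique() == 1).all()

    def test_missing_age_coefficient_rejected(self, cohort300):
        fit = fit_mle(cohort300, "MGM")
        with pytest.raises(KeyError):
            diagnostics_table([fit])
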