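"""Care-quality composite: quartimax rotation, PCA scores, imputation, taus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxemed.carefactor import (
    extract_care_quality,
    kendall_intercorrelations,
    quartimax_criterion,
    quartimax_rotate,
    stochastic_regression_impute,
)
from gxemed.cohort import ADVERSITY_DIMS, QUESTIONNAIRE_DIMS
from .conftest import make_analysis_cohort
from gxemed.simulate import SimulationConfig, simulate_cohort


def _brute_force_pairwise(L, step=0.001):
    """Best single pairwise rotation by exhaustive angle scan."""
    best = quartimax_criterion(L)
    for theta in np.arange(-np.pi / 4, np.pi / 4, step):
        c, s = np.cos(theta), np.sin(theta)
        G = np.array([[c, -s], [s, c]])
        best = max(best, quartimax_criterion(L @ G))
    return best


class TestQuartimax:
    def test_optimal_input_is_fixed_point(self):
        # perfect cluster structure is already quartimax-optimal
        L = np.array([[0.8, 0.0]] * 5 + [[0.0, 0.7]] * 4)
        rot, T = quartimax_rotate(L)
        assert np.abs(np.abs(T) - np.eye(2)).max() < 1e-6  # identity up to sign

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_criterion_beats_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(9, 2))
        rot, T = quartimax_rotate(L)
        assert quartimax_criterion(rot) >= _brute_force_pairwise(L) - 1e-6

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rotation_orthonormal_and_communalities_preserved(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(9, 3))
        rot, T = quartimax_rotate(L)
        assert np.abs(T.T @ T - np.eye(3)).max() < 1e-8
        assert np.abs((rot**2).sum(axis=1) - (L**2).sum(axis=1)).max() < 1e-8
        assert np.abs(rot - L @ T).max() < 1e-10

    def test_single_component_warns_identity(self):
        L = np.array([[0.5], [0.6]])
        with pytest.warns(UserWarning, match="single component"):
            rot, T = quartimax_rotate(L)
        assert np.array_equal(T, np.eye(1))


class TestExtractCareQuality:
    def test_latent_recovery(self):
        loadings = dict.fromkeys(QUESTIONNAIRE_DIMS, 0.0)
        for d in ["ctq_physical_abuse", "ctq_emotional_abuse", "ctq_physical_neglect",
                  "ctq_emotional_neglect", "pbi_overprotection"]:
            loadings[d] = -0.7
        loadings["pbi_maternal_care"] = 0.7
        cfg = SimulationConfig(n_subjects=1000, seed=5, missing_rates={}, factor_loadings=loadings)
        cohort, truth = simulate_cohort(cfg)
        fac = extract_care_quality(cohort[QUESTIONNAIRE_DIMS])
        assert np.corrcoef(fac.scores, truth["care_latent"])[0, 1] > 0.9

    def test_leading_eigenvalue_matches_planted_variance_share(self):
        # six dimensions loading sqrt(0.6) give a 4/9 leading variance share
        cohort, _ = simulate_cohort(SimulationConfig(n_subjects=5000, seed=6, missing_rates={}))
        fac = extract_care_quality(cohort[QUESTIONNAIRE_DIMS])
        assert fac.eigenvalues[0] == pytest.approx(4.0, abs=0.3)
        assert not fac.no_structure

    def test_pure_noise_flags_no_structure(self):
        rng = np.random.default_rng(0)
        q = pd.DataFrame(rng.normal(size=(600, 9)), columns=QUESTIONNAIRE_DIMS)
        with pytest.warns(UserWarning, match="no component"):
            fac = extract_care_quality(q)
        assert fac.no_structure

    def test_adversity_orientation(self, default_cohort):
        cohort, _ = default_cohort
        fac = extract_care_quality(cohort[QUESTIONNAIRE_DIMS])
        for dim in ADVERSITY_DIMS:
            pair = pd.DataFrame({"s": fac.scores, "d": cohort[dim]}).dropna()
            if pair["d"].nunique() > 1:
                assert np.corrcoef(pair["s"], pair["d"])[0, 1] < 0.1

    def test_scores_standardized(self, default_cohort):
        cohort, _ = default_cohort
        fac = extract_care_quality(cohort[QUESTIONNAIRE_DIMS])
        obs = fac.scores.dropna()
        assert obs.mean() == pytest.approx(0.0, abs=1e-10)
        assert obs.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert fac.scores[cohort[QUESTIONNAIRE_DIMS].isna().any(axis=1)].isna().all()

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(1)
        q = pd.DataFrame(rng.normal(size=(100, 9)), columns=QUESTIONNAIRE_DIMS)
        q["pbi_maternal_care"] = 3.0
        with pytest.raises(ValueError, match="pbi_maternal_care"):
            extract_care_quality(q)

    def test_too_few_complete_rows_rejected(self):
        rng = np.random.default_rng(2)
        q = pd.DataFrame(rng.normal(size=(20, 9)), columns=QUESTIONNAIRE_DIMS)
        with pytest.raises(ValueError, match="30"):
            extract_care_quality(q)


class TestStochasticRegressionImpute:
    def _linear_setup(self, n=200, seed=0, missing=30):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 9)), columns=QUESTIONNAIRE_DIMS)
        beta = np.linspace(-1, 1, 9)
        y = pd.Series(X.to_numpy() @ beta)  # exactly linear, no noise
        y_missing = y.copy()
        y_missing.iloc[:missing] = np.nan
        return X, y, y_missing

    def test_no_missing_is_identity(self):
        X, y, _ = self._linear_setup()
        out, flag = stochastic_regression_impute(y, X, rng=0)
        pd.testing.assert_series_equal(out, y)
        assert not flag.any()

    def test_zero_noise_returns_fitted_values_exactly(self):
        X, y, y_missing = self._linear_setup()
        out, flag = stochastic_regression_impute(y_missing, X, rng=0, noise_scale=0.0)
        assert np.abs(out.iloc[:30] - y.iloc[:30]).max() < 1e-8
        assert flag.iloc[:30].all()

    def test_observed_scores_never_altered(self):
        X, y, y_missing = self._linear_setup()
        out, _ = stochastic_regression_impute(y_missing, X, rng=1)
        pd.testing.assert_series_equal(out.iloc[30:], y_missing.iloc[30:])

    def test_imputed_variance_matches_fitted_plus_residual(self):
        """Monte-Carlo: Var(imputed) ~ Var(fitted) + residual variance."""
        rng = np.random.default_rng(7)
        n, reps = 400, 200
        beta = np.linspace(-0.5, 0.5, 9)
        imputed_all = []
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(n, 9)), columns=QUESTIONNAIRE_DIMS)
            y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 0.8, n))
            miss = rng.choice(n, size=int(0.12 * n), replace=False)
            y_missing = y.copy()
            y_missing.iloc[miss] = np.nan
            out, flag = stochastic_regression_impute(y_missing, X, rng=rng)
            imputed_all.extend(out[flag].tolist())
        target = float(beta @ beta) + 0.8**2  # fitted variance + residual variance
        assert np.var(imputed_all) == pytest.approx(target, rel=0.05)


class TestKendall:
    def test_identical_columns_give_unit_tau(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        q = pd.DataFrame({d: x for d in QUESTIONNAIRE_DIMS[:3]})
        taus = kendall_intercorrelations(q, QUESTIONNAIRE_DIMS[:3])
        assert np.allclose(taus, 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        q = pd.DataFrame(rng.normal(size=(1000, 2)), columns=QUESTIONNAIRE_DIMS[:2])
        taus = kendall_intercorrelations(q, QUESTIONNAIRE_DIMS[:2])
        assert abs(taus.iloc[0, 1]) < 0.07

    def test_planted_factor_taus_in_reported_band(self):
        """Six dimensions sharing a common factor show pairwise tau-b
        magnitudes in the 0.2-0.6 band."""
        cohort, _ = make_analysis_cohort(5000, seed=12)
        dims = ["ctq_physical_abuse", "ctq_emotional_abuse", "ctq_physical_neglect",
                "ctq_emotional_neglect", "pbi_maternal_care", "pbi_overprotection"]
        taus = kendall_intercorrelations(cohort, dims)
        off = taus.to_numpy()[~np.eye(len(dims), dtype=bool)]
        assert (np.abs(off) >= 0.2).all() and (np.abs(off) <= 0.6).all()

    def test_constant_column_reported_missing(self):
        q = pd.DataFrame({"a": np.arange(50.0), "b": np.ones(50)})
        taus = kendall_intercorrelations(q, ["a", "b"])
        assert np.isnan(taus.loc["a", "b"])

    def test_too_few_pairs_rejected(self):
        q = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(ValueError, match="10"):
            kendall_intercorrelations(q, ["a", "b"])
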