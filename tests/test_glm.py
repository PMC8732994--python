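"""Demographic tests and covariate-adjusted GLMs against direct-formula
oracles, published summary statistics, and planted effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emodiv.glm import (
    GroupDifferenceModel,
    ModelSpecificationError,
    SymptomAssociationModel,
    fit_glm,
    standardize,
    welch_t_from_summary,
    yates_chi_square,
)
from emodiv.scoring import score_cohort
from emodiv.simulate import generate_cohort, matched_spec
from emodiv.validation import plant_group_score_shift

from oracles import chi2_uncorrected_oracle, ols_normal_equations, welch_oracle, yates_oracle


class TestWelch:
    @pytest.mark.parametrize(
        "summary,expected_t,tol",
        [
            ((11.45, 4.55, 47, 0.41, 1.03, 58), 16.30, 0.01),
            ((9.28, 7.15, 47, 0.24, 0.54, 58), 8.64, 0.01),
            ((19.04, 1.63, 47, 19.24, 2.58, 58), -0.481, 0.005),
        ],
    )
    def test_published_group_rows_reproduce(self, summary, expected_t, tol):
        res = welch_t_from_summary(*summary)
        assert res.t == pytest.approx(expected_t, abs=tol)

    def test_identical_summaries_null(self):
        res = welch_t_from_summary(5.0, 1.2, 30, 5.0, 1.2, 30)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_sign_follows_mean_difference(self):
        assert welch_t_from_summary(2, 1, 10, 1, 1, 10).t > 0
        assert welch_t_from_summary(1, 1, 10, 2, 1, 10).t < 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5),
        s1=st.floats(0.1, 5), s2=st.floats(0.1, 5),
        n1=st.integers(2, 200), n2=st.integers(2, 200),
    )
    def test_matches_direct_formula_oracle(self, m1, m2, s1, s2, n1, n2):
        res = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        t, df = welch_oracle(m1, s1, n1, m2, s2, n2)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, rel=1e-10)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ModelSpecificationError):
            welch_t_from_summary(1, 0, 10, 2, 1, 10)
        with pytest.raises(ModelSpecificationError):
            welch_t_from_summary(1, 1, 1, 2, 1, 10)


class TestChiSquare:
    def test_published_sex_table_requires_yates(self):
        table = [[26, 22], [21, 36]]
        corrected = yates_chi_square(table)
        uncorrected = yates_chi_square(table, correction=False)
        assert corrected.statistic == pytest.approx(2.50, abs=0.01)
        assert uncorrected.statistic == pytest.approx(3.16, abs=0.01)
        assert abs(uncorrected.statistic - 2.50) > 0.5

    def test_perfect_independence_is_zero(self):
        assert yates_chi_square([[10, 10], [10, 10]]).statistic == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    def test_matches_formula_oracle(self, counts):
        table = [[counts[0], counts[1]], [counts[2], counts[3]]]
        assert yates_chi_square(table).statistic == pytest.approx(
            yates_oracle(table), abs=1e-10
        )
        assert yates_chi_square(table, correction=False).statistic == pytest.approx(
            chi2_uncorrected_oracle(table), abs=1e-10
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ModelSpecificationError):
            yates_chi_square([[0, 0], [5, 5]])


class TestStandardize:
    def test_simple_case(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        z = standardize(rng.normal(3, 7, 100))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
        c=st.floats(-10, 10),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, c, seed):
        x = np.random.default_rng(seed).normal(size=20)
        assert np.allclose(
            standardize(a * x + c), np.sign(a) * standardize(x), atol=1e-8
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ModelSpecificationError):
            standardize([2.0, 2.0, 2.0])


class TestFitGlm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        focal = rng.normal(size=1000)
        outcome = 0.5 * focal + rng.normal(scale=0.1, size=1000)
        res = fit_glm(outcome, focal)
        assert 0.45 <= res.b <= 0.55
        assert res.ci_low <= 0.5 <= res.ci_high

    def test_null_effect_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        res = fit_glm(rng.normal(size=1000), rng.normal(size=1000))
        assert res.ci_low <= 0 <= res.ci_high

    def test_duplicated_covariate_raises_naming_columns(self):
        rng = np.random.default_rng(4)
        focal = rng.normal(size=50)
        cov = rng.normal(size=50)
        with pytest.raises(ModelSpecificationError, match="collinear"):
            fit_glm(
                rng.normal(size=50),
                focal,
                np.column_stack([cov, cov]),
                covariate_names=("a", "a_copy"),
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5000), n=st.integers(10, 60), p=st.integers(0, 3))
    def test_matches_normal_equations_oracle(self, seed, n, p):
        rng = np.random.default_rng(seed)
        focal = rng.normal(size=n)
        covs = rng.normal(size=(n, p)) if p else None
        y = rng.normal(size=n)
        res = fit_glm(y, focal, covs)
        X = focal[:, None] if covs is None else np.column_stack([focal, covs])
        beta = ols_normal_equations(y, X)
        assert res.b == pytest.approx(beta[1], abs=1e-8)

    def test_ci_coverage_on_nulls(self):
        # 95% CI empirical coverage across 500 null simulations
        rng = np.random.default_rng(6)
        covered = 0
        reps = 500
        for _ in range(reps):
            focal = rng.normal(size=40)
            y = rng.normal(size=40)
            res = fit_glm(y, focal)
            covered += res.ci_low <= 0 <= res.ci_high
        assert 0.92 <= covered / reps <= 0.98


@pytest.fixture(scope="module")
def null_scores():
    spec = matched_spec(n_chr=500, n_hc=500, seed=21)
    return score_cohort(generate_cohort(spec))


@pytest.fixture(scope="module")
def scores():
    from emodiv.simulate import default_spec

    spec = default_spec(seed=22)
    spec.n_chr = 400
    spec.n_hc = 100
    return score_cohort(generate_cohort(spec))


class TestGroupDifferenceModel:
    def test_planted_deficit_detected(self, null_scores):
        shifted, true_b = plant_group_score_shift(null_scores, "positive", -0.5)
        res = GroupDifferenceModel(shifted, "positive").fit()
        assert res.b < 0
        assert res.ci_high < 0
        assert res.ci_low <= true_b <= res.ci_high

    def test_null_total_metric_r2_near_zero(self, null_scores):
        res = GroupDifferenceModel(null_scores, "total").fit()
        assert res.r2_partial < 0.02

    def test_single_group_rejected(self, null_scores):
        chr_only = null_scores[null_scores["group"] == "CHR"]
        with pytest.raises(ModelSpecificationError):
            GroupDifferenceModel(chr_only, "positive")

    def test_total_metric_uses_both_valence_means(self, null_scores):
        res = GroupDifferenceModel(null_scores, "total").fit()
        assert set(res.covariates) == {
            "antipsychotic",
            "mean_positive_emotion",
            "mean_negative_emotion",
        }


class TestSymptomAssociationModel:
    def test_planted_negative_dependence_detected(self, scores):
        # default loadings depress symptoms when positive emotion is rich;
        # impose a direct negative coupling instead for a known sign
        rigged = scores.copy()
        rng = np.random.default_rng(7)
        z = standardize(rigged["diversity_positive"])
        rigged["sips_total_positive"] = np.round(
            10 - 3 * z + rng.normal(scale=2, size=len(rigged))
        ).clip(0, 30)
        res = SymptomAssociationModel(rigged, "positive", "positive").fit()
        assert res.b < 0
        assert res.ci_high < 0

    def test_independent_symptoms_ci_covers_zero(self, scores):
        rigged = scores.copy()
        rng = np.random.default_rng(8)
        rigged["sips_total_positive"] = rng.integers(0, 20, size=len(rigged))
        res = SymptomAssociationModel(rigged, "positive", "positive").fit()
        assert res.ci_low <= 0 <= res.ci_high

    def test_chr_only_flag_changes_n(self, scores):
        res_chr = SymptomAssociationModel(scores, "positive", "positive", True).fit()
        res_all = SymptomAssociationModel(scores, "positive", "positive", False).fit()
        assert res_chr.n == (scores["group"] == "CHR").sum()
        assert res_all.n == len(scores)

    def test_too_few_chr_rejected(self, scores):
        small = scores[scores["group"] == "CHR"].head(5)
        with pytest.raises(ModelSpecificationError):
            SymptomAssociationModel(small, "positive", "positive", True)
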