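import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methbp import datasets
from methbp.association import (
    COVARIATES_BP,
    COVARIATES_HTN,
    SummaryStats,
    chi_square_2x2,
    classify_hypertension,
    compute_bmi,
    fit_linear_bp,
    fit_logistic_htn,
    mean_bp,
    two_sample_t_summary,
)


class TestClassifyHypertension:
    @pytest.mark.parametrize(
        "sbp,dbp,treated,expected",
        [
            (140, 80, False, True),
            (139, 89, False, False),
            (120, 70, True, True),
            (120, 90, False, True),
        ],
    )
    def test_rule(self, sbp, dbp, treated, expected):
        assert classify_hypertension(sbp, dbp, treated) is expected

    def test_vectorized(self):
        out = classify_hypertension([150, 100], [70, 70], [False, False])
        assert out.tolist() == [True, False]


class TestPhenotypeHelpers:
    def test_mean_bp(self):
        assert mean_bp([120, 122, 124]) == 122
        assert mean_bp([90, 90, 90]) == 90
        assert mean_bp([100, 110, 120]) == 110

    def test_mean_bp_wrong_count(self):
        with pytest.raises(ValueError):
            mean_bp([120, 122])

    def test_bmi(self):
        assert compute_bmi(81, 180) == pytest.approx(25.0)
        assert compute_bmi(50, 200) == pytest.approx(12.5)

    def test_bmi_nonpositive(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 170)


class TestTwoSampleTSummary:
    def test_reference_cpg3(self):
        s = datasets.group_summary("discovery", "CpG3")
        t, df, p = two_sample_t_summary(s)
        assert df == 2496
        assert round(p, 3) == 0.024

    def test_reference_cpg9(self):
        _, _, p = two_sample_t_summary(datasets.group_summary("discovery", "CpG9"))
        assert round(p, 3) == 0.027

    def test_equal_means(self):
        t, _, p = two_sample_t_summary(
            SummaryStats(n1=10, n2=10, mean1=5, mean2=5, sd1=1, sd2=1)
        )
        assert t == 0 and p == 1

    def test_matches_scipy_from_stats(self):
        s = SummaryStats(n1=34, n2=55, mean1=1.2, mean2=0.4, sd1=2.0, sd2=1.7)
        t, df, p = two_sample_t_summary(s)
        t2, p2 = stats.ttest_ind_from_stats(
            s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=True
        )
        assert t == pytest.approx(t2, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-12)

    def test_agrees_with_raw_data_t_test(self):
        # construct raw samples with exactly the requested moments
        rng = np.random.default_rng(0)

        def with_moments(n, mean, sd):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = with_moments(40, 3.0, 1.4)
        b = with_moments(55, 2.2, 1.9)
        s = SummaryStats(n1=40, n2=55, mean1=3.0, mean2=2.2, sd1=1.4, sd2=1.9)
        _, _, p_summary = two_sample_t_summary(s)
        _, p_raw = stats.ttest_ind(a, b, equal_var=True)
        assert abs(p_summary - p_raw) < 1e-10

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SummaryStats(n1=1, n2=10, mean1=0, mean2=0, sd1=1, sd2=1)
        with pytest.raises(ValueError):
            SummaryStats(n1=5, n2=10, mean1=0, mean2=0, sd1=0, sd2=1)


class TestChiSquare2x2:
    def test_reference_smoking_counts(self):
        d = datasets.DISCOVERY_SMOKING_2X2
        stat, p = chi_square_2x2(
            d["smoker_nonhbp"], d["nonsmoker_nonhbp"],
            d["smoker_hbp"], d["nonsmoker_hbp"],
        )
        assert p < 0.001

    def test_proportional_table(self):
        stat, p = chi_square_2x2(10, 20, 30, 60)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_uniform_table(self):
        stat, _ = chi_square_2x2(5, 5, 5, 5)
        assert stat == 0

    def test_matches_scipy(self):
        stat, p = chi_square_2x2(12, 34, 25, 19)
        s2, p2, _, _ = stats.chi2_contingency(
            np.array([[12, 34], [25, 19]]), correction=False
        )
        assert stat == pytest.approx(s2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    def test_zero_margin(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestFitLinearBP:
    def test_matches_statsmodels(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0]
        covs = ph[COVARIATES_BP]
        r = fit_linear_bp(ph["sbp"].to_numpy(), meth, covs)
        X = sm.add_constant(
            pd.concat([pd.Series(meth / 5, name="m5"), covs.reset_index(drop=True)], axis=1)
        )
        fit = sm.OLS(ph["sbp"].to_numpy(), X).fit()
        assert r.beta_per5 == pytest.approx(fit.params["m5"], rel=1e-8)
        assert r.se == pytest.approx(fit.bse["m5"], rel=1e-8)
        assert r.p == pytest.approx(fit.pvalues["m5"], rel=1e-6)

    def test_simple_regression_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 10, 200)
        y = 3.0 + 0.2 * x + rng.normal(0, 1, 200)
        r = fit_linear_bp(y, x, covariates=None)
        x5 = x / 5
        slope = np.cov(x5, y, ddof=1)[0, 1] / np.var(x5, ddof=1)
        assert r.beta_per5 == pytest.approx(slope, abs=1e-10)

    def test_constant_methylation_errors(self, small_cohort):
        ph = small_cohort.phenotypes
        const = np.full(len(ph), 42.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_bp(ph["sbp"].to_numpy(), const, ph[COVARIATES_BP])

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_linear_bp(np.arange(10.0), np.arange(10.0) + 1, None)

    def test_complete_case_count(self, small_cohort):
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0].copy()
        meth[:5] = np.nan
        r = fit_linear_bp(ph["sbp"].to_numpy(), meth, ph[COVARIATES_BP])
        assert r.n_used == len(ph) - 5

    def test_type_I_error_calibrated(self):
        # truth 0: rejection rate at alpha=.05 over replicate fits
        rng = np.random.default_rng(99)
        n, reps = 500, 1000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(40, 6, n)
            z = rng.normal(0, 1, n)
            y = 100 + 2 * z + rng.normal(0, 10, n)
            r = fit_linear_bp(y, x, pd.DataFrame({"z": z}))
            rejections += r.p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_covariate_order_invariance(self, small_cohort):
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 2]
        r1 = fit_linear_bp(ph["sbp"].to_numpy(), meth, ph[COVARIATES_BP])
        r2 = fit_linear_bp(ph["sbp"].to_numpy(), meth, ph[COVARIATES_BP[::-1]])
        assert r1.beta_per5 == pytest.approx(r2.beta_per5, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)

    def test_covariate_rescaling_leaves_p_unchanged(self, small_cohort):
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0]
        covs = ph[COVARIATES_BP].copy()
        r1 = fit_linear_bp(ph["sbp"].to_numpy(), meth, covs)
        covs2 = covs.copy()
        covs2["age"] = covs2["age"] * 12 + 3
        r2 = fit_linear_bp(ph["sbp"].to_numpy(), meth, covs2)
        assert r1.p == pytest.approx(r2.p, abs=1e-8)
        assert r1.beta_per5 == pytest.approx(r2.beta_per5, abs=1e-8)


class TestFitLogisticHtn:
    def test_matches_statsmodels(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0]
        covs = ph[COVARIATES_HTN]
        r = fit_logistic_htn(ph["hypertension"].to_numpy(), meth, covs)
        X = sm.add_constant(
            pd.concat([pd.Series(meth / 5, name="m5"), covs.reset_index(drop=True)], axis=1)
        )
        fit = sm.Logit(ph["hypertension"].to_numpy(), X).fit(disp=0)
        assert r.beta_per5 == pytest.approx(fit.params["m5"], rel=1e-6)
        assert r.se == pytest.approx(fit.bse["m5"], rel=1e-5)

    def test_single_class_errors(self, small_cohort):
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0]
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_htn(np.ones(len(ph)), meth, ph[COVARIATES_HTN])

    def test_scale_equivariance_per5(self, small_cohort):
        ph = small_cohort.phenotypes
        meth = small_cohort.methylation.values[:, 0]
        r1 = fit_logistic_htn(ph["hypertension"].to_numpy(), meth, ph[COVARIATES_HTN])
        # multiplying methylation by 10 divides the per-5% log-odds by 10
        r2 = fit_logistic_htn(ph["hypertension"].to_numpy(), meth * 10, ph[COVARIATES_HTN])
        assert r2.beta_per5 * 10 == pytest.approx(r1.beta_per5, rel=1e-6)
        assert r2.p == pytest.approx(r1.p, abs=1e-8)

    def test_perfect_separation_detected(self):
        y = np.array([0] * 50 + [1] * 50, dtype=float)
        x = np.array([10.0] * 50 + [90.0] * 50)
        with pytest.raises(ValueError, match="separation|collinear"):
            fit_logistic_htn(y, x, None)

    def test_ci_brackets_or(self, small_cohort):
        ph = small_cohort.phenotypes
        r = fit_logistic_htn(
            ph["hypertension"].to_numpy(),
            small_cohort.methylation.values[:, 0],
            ph[COVARIATES_HTN],
        )
        lo, hi = r.ci95
        assert lo < r.or_value < hi
        assert np.exp(r.beta_per5) == pytest.approx(r.or_value)


@given(
    n1=st.integers(5, 500),
    n2=st.integers(5, 500),
    d=st.floats(-3, 3),
    sd1=st.floats(0.1, 5),
    sd2=st.floats(0.1, 5),
)
@settings(max_examples=50, deadline=None)
def test_t_summary_p_in_range(n1, n2, d, sd1, sd2):
    s = SummaryStats(n1=n1, n2=n2, mean1=d, mean2=0.0, sd1=sd1, sd2=sd2)
    t, df, p = two_sample_t_summary(s)
    assert 0 <= p <= 1
    assert df == n1 + n2 - 2
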