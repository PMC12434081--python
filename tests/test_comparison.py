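"""Agreement statistics: RMSE, relative bias, Bland-Altman, Friedman, omnibus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from bsaecho.comparison import (
    bland_altman,
    compare_equations,
    friedman_exact_p,
    friedman_statistic,
    friedman_test,
    pearson_r,
    relative_bias_and_sd,
    rmse,
)
from bsaecho.equations import METHOD_IDS
from bsaecho.simulate import (
    CriterionModel,
    SexAnthropometry,
    SimulationConfig,
    simulate_cohort,
)

positive_vec = arrays(
    float,
    st.integers(5, 12),
    elements=st.floats(1.2, 2.6, allow_nan=False),
)


class TestRmse:
    def test_identity_and_constant_shift(self, rng):
        ref = 1.5 + 0.2 * rng.random(20)
        assert rmse(ref, ref) == 0.0
        assert rmse(ref + 0.1, ref) == pytest.approx(0.1)

    def test_matches_elementwise_brute_force(self, rng):
        pred = 1.5 + 0.3 * rng.random(5)
        ref = 1.5 + 0.3 * rng.random(5)
        brute = (sum((p - r) ** 2 for p, r in zip(pred, ref)) / 5) ** 0.5
        assert rmse(pred, ref) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch_and_empty_raise(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            rmse([], [])

    @given(pred=positive_vec, ref=positive_vec)
    def test_decomposes_into_bias_and_spread(self, pred, ref):
        """RMSE² = (mean difference)² + population variance of differences."""
        n = min(len(pred), len(ref))
        pred, ref = pred[:n], ref[:n]
        diff = pred - ref
        assert rmse(pred, ref) ** 2 == pytest.approx(
            diff.mean() ** 2 + diff.var(ddof=0), rel=1e-9, abs=1e-12
        )


class TestRelativeBias:
    def test_pure_multiplicative_bias(self, rng):
        ref = 1.5 + 0.2 * rng.random(30)
        bias, sd = relative_bias_and_sd(1.05 * ref, ref)
        assert bias == pytest.approx(5.0)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert relative_bias_and_sd(ref, ref) == pytest.approx((0.0, 0.0))

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError, match="positive"):
            relative_bias_and_sd([1.0, 1.0], [1.0, 0.0])

    @given(pred=positive_vec, ref=positive_vec, k=st.floats(0.1, 8.0))
    def test_invariant_under_common_rescaling(self, pred, ref, k):
        n = min(len(pred), len(ref))
        pred, ref = pred[:n], ref[:n]
        a = relative_bias_and_sd(pred, ref)
        b = relative_bias_and_sd(k * pred, k * ref)
        assert a[0] == pytest.approx(b[0], rel=1e-9, abs=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9, abs=1e-9)


class TestBlandAltman:
    def test_constant_offset(self, rng):
        ref = 1.5 + 0.2 * rng.random(25)
        ba = bland_altman(ref + 0.07, ref)
        assert ba.mean_diff == pytest.approx(0.07)
        assert ba.loa_high - ba.loa_low == pytest.approx(0.0, abs=1e-9)
        assert ba.prop_bias_r is None and ba.prop_bias_p is None

    @given(pred=positive_vec, ref=positive_vec)
    def test_mean_diff_linearity(self, pred, ref):
        n = min(len(pred), len(ref))
        pred, ref = pred[:n], ref[:n]
        ba = bland_altman(pred, ref)
        assert ba.mean_diff == pytest.approx(pred.mean() - ref.mean(), abs=1e-12)
        assert ba.loa_low <= ba.loa_high

    def test_proportional_bias_detected(self, rng):
        ref = np.linspace(1.3, 2.3, 40) + 0.01 * rng.standard_normal(40)
        ba = bland_altman(1.1 * ref, ref)
        assert ba.prop_bias_r > 0.9
        assert ba.prop_bias_p < 1e-6


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.1, 1.9, 3.5, 4.0, 7.7])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        brute = cov / (x.std() * y.std())
        assert pearson_r(x, y) == pytest.approx(brute, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFriedman:
    def test_identical_columns_give_zero(self):
        matrix = np.tile(np.array([[1.7], [1.8], [1.9]]), (1, 4))
        stat, p = friedman_test(matrix)
        assert stat == 0.0
        assert p == 1.0

    def test_row_shift_invariance(self, rng):
        matrix = rng.random((6, 4))
        shifted = matrix.copy()
        shifted[2] += 100.0
        assert friedman_statistic(shifted) == pytest.approx(
            friedman_statistic(matrix)
        )

    def test_matches_scipy_with_and_without_ties(self, rng):
        for trial in range(5):
            matrix = rng.random((8, 5))
            if trial % 2:  # inject ties
                matrix = np.round(matrix, 1)
            expected = stats.friedmanchisquare(*matrix.T.tolist())
            stat, p = friedman_test(matrix)
            assert stat == pytest.approx(expected.statistic, rel=1e-10)
            assert p == pytest.approx(expected.pvalue, rel=1e-10)

    def test_exact_p_matches_independent_enumeration(self):
        """3 subjects x 3 methods with strict orderings: the exact permutation
        p must equal a from-scratch enumeration over all 6³ rank tables."""
        matrix = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [3.0, 1.0, 2.0]])

        def brute_stat(rows):
            ranks = np.array([stats.rankdata(r) for r in rows])
            rj = ranks.sum(axis=0)
            n, k = ranks.shape
            return 12 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)

        observed = brute_stat(matrix)
        assert friedman_statistic(matrix) == pytest.approx(observed)

        perms = list(itertools.permutations(range(3)))
        count = total = 0
        for combo in itertools.product(perms, repeat=3):
            rows = [matrix[i, list(p)] for i, p in enumerate(combo)]
            total += 1
            if brute_stat(rows) >= observed - 1e-12:
                count += 1
        assert friedman_exact_p(matrix) == pytest.approx(count / total)

    def test_degenerate_dimensions_raise(self):
        with pytest.raises(ValueError):
            friedman_statistic(np.ones((1, 5)))
        with pytest.raises(ValueError):
            friedman_statistic(np.ones((5, 1)))


def _cohort(reference, bias, cv, n_male=400, seed=11):
    config = SimulationConfig(
        n_male=n_male,
        n_female=0,
        seed=seed,
        male=SexAnthropometry(177.0, 7.0, bmi_mean=21.4, bmi_sd=1.78),
        female=SexAnthropometry(165.0, 6.0, bmi_mean=20.8, bmi_sd=1.56),
        criterion=CriterionModel(
            reference_method=reference,
            bias_pct={"male": bias, "female": bias},
            noise_cv_pct={"male": cv, "female": cv},
        ),
    )
    return simulate_cohort(config)


class TestCompareEquations:
    def test_truth_equals_one_method_wins_rmse(self):
        """When the criterion is a noisy copy of one equation, that equation
        attains the minimum RMSE."""
        cohort = _cohort("mosteller", bias=0.0, cv=3.0)
        report = compare_equations(cohort, sex="male")
        assert report.rank_by_rmse()[0] == "mosteller"

    def test_bias_sign_recovered(self):
        cohort = _cohort("dubois", bias=4.0, cv=3.0, n_male=2000)
        report = compare_equations(cohort, sex="male")
        assert report.table.loc["dubois", "bias_pct"] == pytest.approx(4.0, abs=0.35)

    def test_all_male_equations_overestimate_under_study_conditions(self):
        """Criterion biased low vs the most accurate equation reproduces the
        all-positive-bias pattern seen in male athletes."""
        from bsaecho.simulate import default_imaging_config

        cohort = simulate_cohort(default_imaging_config(5))
        report = compare_equations(cohort, sex="male")
        assert (report.table["bias_pct"] > 0).all()

    def test_identical_subjects_collapse_to_point_estimates(self):
        cohort = pd.DataFrame(
            {
                "id": [f"t{i}" for i in range(5)],
                "sex": ["male"] * 5,
                "weight_kg": [70.0] * 5,
                "height_cm": [180.0] * 5,
                "criterion_bsa_m2": [1.85] * 5,
            }
        )
        report = compare_equations(cohort, sex="male")
        t = report.table
        assert (t["est_median"] == t["est_q1"]).all()
        assert (t["est_median"] == t["est_q3"]).all()
        assert (t["sd_diff_pct"].abs() < 1e-9).all()

    def test_requires_criterion_and_minimum_subjects(self, small_cohort):
        with pytest.raises(ValueError, match="criterion"):
            compare_equations(small_cohort.drop(columns="criterion_bsa_m2"))
        with pytest.raises(ValueError, match="at least 3"):
            compare_equations(small_cohort.iloc[:2])

    def test_report_is_complete_and_consistent(self, small_cohort):
        report = compare_equations(small_cohort)
        assert set(report.table.index) == set(METHOD_IDS)
        assert (report.table["rmse"] >= 0).all()
        assert report.table["pcc"].abs().max() <= 1.0
        assert (report.table["ba_loa_low"] <= report.table["ba_loa_high"]).all()
        assert report.omnibus["branch"] in ("repeated_measures_anova", "friedman")
        d = report.to_dict()
        assert d["n_subjects"] == 6 and len(d["methods"]) == 10
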