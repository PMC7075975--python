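import numpy as np
import pandas as pd
import pytest

from duogrs.cohort_analysis import (
    ConvergenceError,
    compare_groups,
    effect_ratio,
    excess_or_ratio,
    fit_linear,
    fit_logistic,
    run_case_cohort,
    run_exposure_cohort,
    validation_correlations,
)


class TestFitLinear:
    def test_identity_fit(self):
        r = fit_linear([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.estimate == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_exact_line(self):
        r = fit_linear([1.0, 3.0, 5.0], [0.0, 1.0, 2.0])
        assert r.estimate == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        r = fit_linear(y, x)
        X = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.estimate == pytest.approx(beta[1], abs=1e-10)

    def test_constant_determinant_is_hard_error(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestFitLogistic:
    def test_two_by_two_table_reproduces_cross_product_or(self):
        # 20/80 exposed cases/controls vs 10/90: OR = (20*90)/(80*10) = 2.25
        case = np.repeat([1, 1, 0, 0], [20, 80, 10, 90])
        x = np.repeat([1, 0, 1, 0], [20, 80, 10, 90])
        r = fit_logistic(case, x)
        assert r.estimate == pytest.approx(2.25, abs=1e-8)

    def test_permuted_determinant_gives_null_or(self):
        rng = np.random.default_rng(12)
        case = np.repeat([0, 1], 200)
        x = rng.permutation(np.linspace(-2, 2, 400))
        r = fit_logistic(case, x)
        assert r.ci_low < 1 < r.ci_high

    def test_complete_separation_raises(self):
        case = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        with pytest.raises(ConvergenceError):
            fit_logistic(case, x)

    def test_single_class_outcome_is_hard_error(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic([1, 1, 1], [0.1, 0.2, 0.3])


def _grouped_frames(n=300, effect=1.2, seed=3):
    rng = np.random.default_rng(seed)
    ref = pd.DataFrame({
        "duo_id": [f"r{i}" for i in range(n)],
        "det_sd": rng.normal(size=n),
        "child_overweight": rng.random(n) < 0.1,
    })
    mo = pd.DataFrame({
        "duo_id": [f"m{i}" for i in range(n)],
        "det_sd": rng.normal(size=n),
    })
    mo["child_overweight"] = rng.random(n) < 1 / (1 + np.exp(-(-1.5 + effect * mo.det_sd)))
    return ref, mo


class TestDesigns:
    def test_case_cohort_rejects_overlapping_duos(self):
        ref, _ = _grouped_frames()
        with pytest.raises(ValueError, match="overlap"):
            run_case_cohort(ref, ref, ["det_sd"])

    def test_case_cohort_fits_one_model_per_determinant(self):
        ref, mo = _grouped_frames()
        results = run_case_cohort(ref, mo, ["det_sd"])
        assert len(results) == 1
        assert results[0].scale == "odds_ratio"

    def test_exposure_cohort_reports_group_or_first_and_no_interaction_fields(self):
        ref, mo = _grouped_frames()
        results = run_exposure_cohort(ref, mo, ["det_sd"], with_interaction=False)
        assert results[0].determinant == "group_indicator"
        assert all(r.interaction is None for r in results)

    def test_exposure_cohort_interaction_recovers_group_specific_effects(self):
        rng = np.random.default_rng(7)
        n = 2000
        ref = pd.DataFrame({"duo_id": [f"r{i}" for i in range(n)],
                            "det_sd": rng.normal(size=n)})
        ref["child_overweight"] = rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 1.0 * ref.det_sd)))
        mo = pd.DataFrame({"duo_id": [f"m{i}" for i in range(n)],
                           "det_sd": rng.normal(size=n)})
        mo["child_overweight"] = rng.random(n) < 0.35  # no effect within MO group
        (res,) = run_exposure_cohort(ref, mo, ["det_sd"], with_interaction=True)[1:]
        assert res.interaction is not None
        assert res.interaction["or_group0"] > 1.5
        assert abs(np.log(res.interaction["or_group1"])) < 0.3
        assert res.interaction["p_interaction"] < 0.01


class TestRatios:
    @pytest.mark.parametrize("a,b,expected", [
        (0.21, 0.28, 0.75),
        (0.10, 0.18, 0.56),
        (0.42, 0.42, 1.0),
    ])
    def test_effect_ratio(self, a, b, expected):
        assert effect_ratio(a, b) == expected

    def test_effect_ratio_is_scale_free(self):
        assert effect_ratio(0.21 * 7, 0.28 * 7) == effect_ratio(0.21, 0.28)

    @pytest.mark.parametrize("a,b,expected", [
        (1.30, 2.01, 0.30),
        (1.30, 1.64, 0.47),
        (1.0, 2.0, 0.0),
    ])
    def test_excess_or_ratio(self, a, b, expected):
        assert excess_or_ratio(a, b) == expected

    def test_invalid_denominators(self):
        with pytest.raises(ZeroDivisionError):
            effect_ratio(0.2, 0.0)
        with pytest.raises(ValueError):
            excess_or_ratio(1.3, 1.0)


class TestValidationCorrelations:
    def test_child_score_correlates_perfectly_with_transmitted_sum(
            self, small_cohort, small_calls):
        from duogrs.grs_scores import build_score_set

        calls, _ = small_calls
        scores = build_score_set(small_cohort.observed, calls, small_cohort.panel)
        complete = np.asarray(calls.called.all(axis=1))
        s = scores[complete]
        r = np.corrcoef(s.child_count,
                        s.maternal_transmitted_count + s.paternal_transmitted_count)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_report_contains_expectations_and_symmetric_matrix(
            self, small_cohort, small_calls):
        from duogrs.grs_scores import build_score_set

        calls, _ = small_calls
        scores = build_score_set(small_cohort.observed, calls, small_cohort.panel)
        rep = validation_correlations(scores)
        np.testing.assert_allclose(rep.correlations, rep.correlations.T)
        np.testing.assert_allclose(np.diag(rep.correlations), 1.0)
        assert {"maternal~child", "maternal_non_transmitted~child"} <= set(rep.expected.pair)


class TestCompareGroups:
    def test_identical_samples_are_null(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_equal_proportions_give_zero_z(self):
        a = [1, 0] * 50
        b = [0, 1] * 50
        stat, p = compare_groups(a, b)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_welch_formula(self):
        a = np.array([15.2, 16.1, 14.8, 15.9, 16.4])
        b = np.array([17.0, 16.5, 17.8, 18.1])
        stat, _ = compare_groups(a, b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert stat == pytest.approx((a.mean() - b.mean()) / se, abs=1e-10)

    def test_empty_group_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups([], [1.0])
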