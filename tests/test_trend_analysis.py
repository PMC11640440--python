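import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trendkit import (
    InputError,
    absolute_difference,
    compute_deviations,
    evaluate_cohort,
    macro_average,
    pair_features,
    paired_t_test,
    relative_difference_pct,
)
from trendkit.trend_analysis import (
    FLAG_DEGENERATE,
    FLAG_INSUFFICIENT_N,
    FLAG_ZERO_RULE,
    SIG_HIGH,
    SIG_LOW,
    SIG_NONE,
    significance_class,
)


def feature_table(patient, condition, pairs):
    """pairs: list of (structure, metric, value)."""
    return pd.DataFrame(
        [
            {"patient_id": patient, "condition": condition, "structure": s, "metric": m, "value": v}
            for s, m, v in pairs
        ],
        columns=["patient_id", "condition", "structure", "metric", "value"],
    )


class TestPairFeatures:
    def test_feature_missing_post_is_dropped(self):
        pre = feature_table("p1", "pre", [("liver", "hu_mean", 40.0), ("liver", "hu_max", 90.0)])
        post = feature_table("p1", "post", [("liver", "hu_max", 80.0)])
        paired = pair_features(pre, post)
        assert len(paired) == 1
        assert paired.iloc[0]["metric"] == "hu_max"

    def test_identical_feature_sets(self):
        rows = [(f"s{i}", m, float(i)) for i in range(2) for m in
                ("volume_ml", "hu_sum", "hu_q1", "hu_q3", "hu_mean", "hu_median", "hu_min", "hu_max")]
        paired = pair_features(feature_table("p", "pre", rows), feature_table("p", "post", rows))
        assert len(paired) == 16

    def test_partial_overlap(self):
        pre = feature_table("p", "pre", [(f"s{i}", "hu_mean", 1.0) for i in range(10)])
        post = feature_table("p", "post", [(f"s{i}", "hu_mean", 2.0) for i in range(5, 12)])
        paired = pair_features(pre, post)
        assert len(paired) == 5
        assert len(paired) <= min(len(pre), len(post))

    def test_drop_is_symmetric(self):
        pre = feature_table("p", "pre", [("a", "hu_mean", 1.0), ("b", "hu_mean", 2.0)])
        post = feature_table("p", "post", [("b", "hu_mean", 3.0), ("c", "hu_mean", 4.0)])
        fwd = pair_features(pre, post)
        rev = pair_features(post.assign(condition="pre"), pre.assign(condition="post"))
        assert set(zip(fwd["structure"], fwd["metric"])) == set(zip(rev["structure"], rev["metric"]))

    def test_patient_mismatch_fatal(self):
        pre = feature_table("p1", "pre", [("a", "hu_mean", 1.0)])
        post = feature_table("p2", "post", [("a", "hu_mean", 1.0)])
        with pytest.raises(InputError, match="patient"):
            pair_features(pre, post)


class TestDifferences:
    @pytest.mark.parametrize("pre,post,expected", [(100, 80, -20), (7.5, 7.5, 0), (-50, -60, -10)])
    def test_absolute(self, pre, post, expected):
        assert absolute_difference(pre, post) == expected

    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (100, 80, -20.0),
            (0, 5, 0.0),     # zero rule: pre = 0
            (5, 0, 0.0),     # zero rule: post = 0
            (0, 0, 0.0),
            (200, 231.1, 15.55),
        ],
    )
    def test_relative(self, pre, post, expected):
        assert relative_difference_pct(pre, post) == pytest.approx(expected, abs=1e-12)

    def test_signs_agree_for_positive_values(self, rng):
        for _ in range(100):
            pre, post = rng.uniform(0.1, 100, size=2)
            a = absolute_difference(pre, post)
            r = relative_difference_pct(pre, post)
            assert a == 0 or np.sign(a) == np.sign(r)

    def test_compute_deviations_flags_zero_rule(self):
        paired = pd.DataFrame(
            {
                "patient_id": ["p", "p"],
                "structure": ["a", "b"],
                "metric": ["hu_mean", "hu_mean"],
                "pre": [100.0, 0.0],
                "post": [80.0, 5.0],
            }
        )
        dev = compute_deviations(paired)
        assert dev.loc[0, "rel_diff_pct"] == -20.0 and dev.loc[0, "flags"] == ""
        assert dev.loc[1, "rel_diff_pct"] == 0.0 and dev.loc[1, "flags"] == FLAG_ZERO_RULE
        assert dev.loc[1, "abs_diff"] == 5.0  # absolute difference always defined


class TestMacroAverage:
    def test_simple_mean(self):
        assert macro_average([-10, -20, -30]) == -20

    def test_single_value(self):
        assert macro_average([5]) == 5

    def test_zero_rule_value_participates(self):
        assert macro_average([-10, 0, -20]) == -10

    def test_empty_fatal(self):
        with pytest.raises(InputError):
            macro_average([])


class TestPairedTTest:
    def test_worked_example_df2(self):
        # differences {1, 1, -1}: t = 0.5, and for df=2 the closed-form CDF
        # gives P(T <= t) = 1/2 + t / (2*sqrt(2)*sqrt(1 + t^2/2)) => p = 2/3
        res = paired_t_test([0.0, 0.0, 0.0], [1.0, 1.0, -1.0])
        assert res.t == pytest.approx(0.5, rel=1e-12)
        assert res.df == 2
        t = res.t
        closed_form_p = 2 * (1 - (0.5 + t / (2 * math.sqrt(2) * math.sqrt(1 + t * t / 2))))
        assert res.p == pytest.approx(closed_form_p, rel=1e-12)
        assert res.p == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_no_change_null(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        pre = rng.normal(size=12)
        post = rng.normal(size=12)
        fwd = paired_t_test(pre, post)
        rev = paired_t_test(post, pre)
        assert fwd.t == pytest.approx(-rev.t, rel=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)

    def test_matches_textbook_formula_and_scipy(self, rng):
        for _ in range(50):
            n = rng.integers(3, 40)
            pre = rng.normal(10, 5, size=n)
            post = pre + rng.normal(0.5, 2, size=n)
            res = paired_t_test(pre, post)
            d = post - pre
            t_ref = d.mean() * math.sqrt(n) / d.std(ddof=1)
            assert res.t == pytest.approx(t_ref, rel=1e-12)
            scipy_res = sps.ttest_rel(post, pre)
            assert res.t == pytest.approx(scipy_res.statistic, rel=1e-12)
            assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-12)

    def test_insufficient_n(self):
        res = paired_t_test([1.0], [2.0])
        assert res.p == 1.0 and res.t == 0.0 and res.flag == FLAG_INSUFFICIENT_N

    def test_degenerate_zero_variance_nonzero_mean(self):
        res = paired_t_test([0.0, 0.0], [3.0, 3.0])
        assert res.p == 0.0 and res.flag == FLAG_DEGENERATE and res.t == math.inf

    def test_zero_variance_zero_mean(self):
        res = paired_t_test([4.0, 4.0], [4.0, 4.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            paired_t_test([1.0, 2.0], [1.0])


def _cohort_deviations(values):
    """values: dict patient -> (pre, post) for one feature."""
    rows = []
    for pid, (pre, post) in values.items():
        rows.append({"patient_id": pid, "structure": "s", "metric": "hu_mean",
                     "pre": pre, "post": post})
    return compute_deviations(pd.DataFrame(rows))


class TestEvaluateCohort:
    def test_three_patient_composition(self):
        dev = _cohort_deviations({"p1": (100.0, 90.0), "p2": (100.0, 80.0), "p3": (100.0, 70.0)})
        table = evaluate_cohort(dev)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["mean_rel_diff_pct"] == pytest.approx(-20.0)
        ref = sps.ttest_rel([90.0, 80.0, 70.0], [100.0, 100.0, 100.0])
        assert row["t"] == pytest.approx(ref.statistic, rel=1e-12)
        assert row["p"] == pytest.approx(ref.pvalue, rel=1e-12)
        assert row["n"] == 3

    def test_single_patient_flagged(self):
        dev = _cohort_deviations({"p1": (10.0, 12.0)})
        table = evaluate_cohort(dev)
        row = table.iloc[0]
        assert row["p"] == 1.0 and row["flags"] == FLAG_INSUFFICIENT_N

    def test_bonferroni_scaling(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(100):
            for pid in ("p1", "p2", "p3", "p4"):
                pre = rng.uniform(50, 150)
                rows.append({"patient_id": pid, "structure": f"s{i:03d}", "metric": "hu_mean",
                             "pre": pre, "post": pre * rng.uniform(0.8, 1.2)})
        table = evaluate_cohort(compute_deviations(pd.DataFrame(rows)), bonferroni=True)
        assert len(table) == 100
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, table["p"] * 100), rtol=1e-12
        )
        assert (table["p_bonferroni"] >= table["p"] - 1e-15).all()
        assert (table["p_bonferroni"] <= 1.0).all()

    def test_bonferroni_worked_example(self):
        # m = 100 features, raw p = 0.0004 -> corrected 0.04
        assert min(1.0, 0.0004 * 100) == pytest.approx(0.04)

    def test_significance_classes(self):
        assert significance_class(0.2) == SIG_NONE
        assert significance_class(0.03) == SIG_LOW
        assert significance_class(0.004) == SIG_HIGH
        assert significance_class(0.05) == SIG_NONE   # strict thresholds
        assert significance_class(0.01) == SIG_LOW

    def test_significance_consistent_with_p(self):
        rows = []
        rng = np.random.default_rng(9)
        for i in range(30):
            for pid in range(5):
                pre = rng.uniform(10, 20)
                rows.append({"patient_id": f"p{pid}", "structure": f"s{i}", "metric": "hu_mean",
                             "pre": pre, "post": pre + rng.normal(0.5)})
        table = evaluate_cohort(compute_deviations(pd.DataFrame(rows)))
        for _, row in table.iterrows():
            assert row["significance"] == significance_class(row["p"])

    def test_empty_deviations(self):
        table = evaluate_cohort(pd.DataFrame(columns=["patient_id", "structure", "metric",
                                                      "pre", "post", "abs_diff",
                                                      "rel_diff_pct", "flags"]))
        assert table.empty
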