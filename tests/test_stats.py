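"""Statistical battery: summaries, rank tests, chi-square, odds ratios."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from coroscore import (
    CoronarySegment,
    DichotomizationThresholds,
    Dominance,
    PatientCCTA,
    PlaqueComposition,
    ScorePanel,
    SegmentLesion,
    compare_categorical,
    compare_multi,
    compare_two,
    dichotomize_panel,
    logistic_or,
    summarize_variable,
    tabulate_lesions,
)

from conftest import random_patient


def enumerate_exact_mwu_p(x, y):
    """Independent exact two-sided Mann-Whitney oracle (midrank enumeration)."""
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    center = n1 * n2 / 2
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    dev = abs(u_obs - center)
    hits = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - center) >= dev - 1e-12
    return hits / total


class TestSummaries:
    def test_nonnormal_median_iqr(self):
        s = summarize_variable([1, 2, 3, 4, 5], "nonnormal")
        assert (s["median"], s["q1"], s["q3"]) == (3, 2, 4)

    def test_constant_values_mean_sd(self):
        s = summarize_variable([7.0] * 10, "normal")
        assert s["mean"] == 7.0 and s["sd"] == 0.0

    def test_categorical_count_percent(self):
        vals = [True] * 20 + [False] * 121
        s = summarize_variable(vals, "categorical")
        assert s["count"] == 20
        assert s["percent"] == pytest.approx(14.2, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_variable([], "normal")

    def test_percentile_rule_selectable(self):
        lin = summarize_variable([1, 2, 3, 4], "nonnormal")
        mid = summarize_variable([1, 2, 3, 4], "nonnormal", percentile_method="midpoint")
        assert lin["q1"] == 1.75 and mid["q1"] == 1.5


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        res = compare_two([1, 2, 3], [4, 5, 6])
        assert res.test == "mann-whitney-exact"
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = compare_two([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_tied_small_groups_enumeration_with_midranks(self):
        res = compare_two([1, 2], [1, 2])
        assert math.isfinite(res.statistic)
        assert 0 < res.p_value <= 1
        assert res.p_value == pytest.approx(enumerate_exact_mwu_p([1, 2], [1, 2]))

    def test_exact_matches_independent_enumeration_random(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            x = rng.integers(0, 20, n1).astype(float)
            y = rng.integers(0, 20, n2).astype(float)
            res = compare_two(x, y)
            assert res.p_value == pytest.approx(enumerate_exact_mwu_p(x, y))

    def test_asymptotic_close_to_exact_without_heavy_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 11 - n1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            exact = compare_two(x, y).p_value
            approx = compare_two(x, y, exact_max_n=0).p_value
            assert abs(exact - approx) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two([], [1.0])


class TestKruskalWallis:
    def test_two_groups_h_equals_squared_standardized_u(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=25)
        omnibus = compare_multi({"a": x, "b": y}, posthoc=False)[0]
        mwu = compare_two(x, y, use_continuity=False)
        # H = z^2 for k = 2 (no continuity correction in the z)
        z = sps.norm.isf(mwu.p_value / 2)
        assert omnibus.statistic == pytest.approx(z**2, rel=1e-6)
        assert omnibus.p_value == pytest.approx(mwu.p_value, rel=1e-6)

    def test_three_identical_groups_adjusted_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0] * 3
        results = compare_multi({"a": g, "b": g, "c": g}, posthoc=True)
        for r in results[1:]:
            assert r.adjusted and r.p_value == pytest.approx(1.0)

    def test_four_groups_emit_six_bonferroni_pairs(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(size=20) for k in "abcd"}
        results = compare_multi(groups, posthoc=True)
        pairs = results[1:]
        assert len(pairs) == 6
        seen = {r.groups for r in pairs}
        assert len(seen) == 6

    def test_bonferroni_adjustment_formula(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc=i, size=15) for i, k in enumerate("abc")}
        results = compare_multi(groups, posthoc=True)
        for r in results[1:]:
            raw = float(r.note.split("raw_p=")[1].split(";")[0])
            assert r.p_value == pytest.approx(min(1.0, 3 * raw), rel=1e-4)
            assert r.p_value >= raw

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_multi({"a": [1.0, 2.0]})


class TestChiSquare:
    def test_homogeneous_table_zero_statistic(self):
        res = compare_categorical([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pearson_formula_on_2x2(self):
        a, b, c, d = 1, 73, 20, 121
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = compare_categorical([[a, b], [c, d]])
        assert res.statistic == pytest.approx(hand)
        assert res.statistic == pytest.approx(9.07, abs=0.01)

    def test_degrees_of_freedom(self):
        res = compare_categorical([[5, 6, 7, 8], [8, 7, 6, 5]])
        assert res.df == 3

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[0, 0], [0, 0]])

    def test_low_expected_counts_warn_not_switch(self):
        with pytest.warns(UserWarning, match="expected count"):
            res = compare_categorical([[1, 9], [2, 8]])
        assert res.test == "chi-square"


def make_panel(sis, sss, ct_lesc, obstructive):
    sc = 0.0 if sis == 0 else sss / sis
    return ScorePanel("p", sis, sss, sc, False, ct_lesc, obstructive)


class TestDichotomization:
    @pytest.mark.parametrize(
        "panel,expected",
        [
            (make_panel(6, 6, 12.31, False), (True, True, True, False)),
            (make_panel(3, 5, 8.7, False), (False, False, False, False)),
            (make_panel(0, 0, 0.0, False), (False, False, False, False)),
        ],
    )
    def test_strict_thresholds(self, panel, expected):
        flags = dichotomize_panel(panel)
        assert (
            flags["sis_gt"], flags["sss_gt"], flags["ct_lesc_gt"], flags["obstructive"]
        ) == expected

    def test_thresholds_config_overridable(self):
        flags = dichotomize_panel(
            make_panel(3, 5, 8.7, False),
            DichotomizationThresholds(sis=2, sss=4, ct_lesc=8.0),
        )
        assert flags["sis_gt"] and flags["sss_gt"] and flags["ct_lesc_gt"]


def outcome_group_from_2x2(a, b, c, d):
    """outcome, group arrays for a table: rows exposed/reference, cols +/-."""
    outcome = [True] * a + [False] * b + [True] * c + [False] * d
    group = ["exposed"] * (a + b) + ["ref"] * (c + d)
    return outcome, group


class TestLogisticOdds:
    def test_or_matches_cross_product_ratio(self):
        a, b, c, d = 17, 23, 11, 49
        outcome, group = outcome_group_from_2x2(a, b, c, d)
        (res,) = logistic_or(outcome, group, reference="ref")
        or_hand = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert res.odds_ratio == pytest.approx(or_hand, rel=1e-6)
        assert res.ci_lower == pytest.approx(
            math.exp(math.log(or_hand) - 1.959963984540054 * se), rel=1e-4
        )
        assert res.ci_upper == pytest.approx(
            math.exp(math.log(or_hand) + 1.959963984540054 * se), rel=1e-4
        )

    def test_equal_proportions_give_unit_or(self):
        outcome, group = outcome_group_from_2x2(10, 30, 10, 30)
        (res,) = logistic_or(outcome, group, reference="ref")
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_separation_flagged_not_silently_estimated(self):
        outcome = [True] * 10 + [True] * 4 + [False] * 6 + [True] * 5 + [False] * 5
        group = ["sep"] * 10 + ["other"] * 10 + ["ref"] * 10
        results = logistic_or(outcome, group, reference="ref")
        by_group = {r.group: r for r in results}
        assert by_group["sep"].separated
        assert math.isnan(by_group["sep"].odds_ratio)
        assert not by_group["other"].separated
        assert math.isfinite(by_group["other"].odds_ratio)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_or([True, True], ["a", "b"], reference="a")

    def test_multigroup_matches_pairwise_2x2(self):
        rng = np.random.default_rng(8)
        groups = ["ref"] * 60 + ["g1"] * 50 + ["g2"] * 40
        probs = {"ref": 0.2, "g1": 0.4, "g2": 0.6}
        outcome = [bool(rng.random() < probs[g]) for g in groups]
        results = logistic_or(outcome, groups, reference="ref")
        counts = {
            g: (
                sum(1 for o, gg in zip(outcome, groups) if gg == g and o),
                sum(1 for o, gg in zip(outcome, groups) if gg == g and not o),
            )
            for g in ("ref", "g1", "g2")
        }
        c, d = counts["ref"]
        for r in results:
            a, b = counts[r.group]
            assert r.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-5)


class TestTabulateLesions:
    def test_empty_cohort_all_zero(self):
        df = tabulate_lesions({"control": []})
        assert df["count"].sum() == 0

    def test_worked_example_margins(self, worked_example):
        df = tabulate_lesions({"dm": [worked_example]})
        seg_total = df[df.block == "segment"]["count"].sum()
        sev = df[df.block == "severity"].set_index("row")["count"]
        comp = df[df.block == "composition"].set_index("row")["count"]
        assert seg_total == 6
        assert sev["non_obstructive"] == 6 and sev["obstructive"] == 0
        assert comp["non_calcified_or_mixed"] == 3 and comp["calcified"] == 3

    def test_margins_conserved_on_random_cohort(self):
        rng = np.random.default_rng(21)
        groups = {
            "a": [random_patient(rng) for _ in range(15)],
            "b": [random_patient(rng) for _ in range(10)],
        }
        df = tabulate_lesions(groups)
        for g in groups:
            sub = df[df.group == g]
            seg = sub[sub.block == "segment"]["count"].sum()
            sev = sub[sub.block == "severity"]["count"].sum()
            comp = sub[sub.block == "composition"]["count"].sum()
            assert seg == sev == comp
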