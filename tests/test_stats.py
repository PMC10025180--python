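"""Statistics: exactness against enumeration oracles, routing, matching."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from articuspace.stats import (
    age_stratum,
    assemble_group_table,
    chi_squared_proportions,
    compare_groups,
    correlation_table,
    match_case_control,
    percent_difference,
    shapiro_normality,
    spearman_corr,
)


class TestShapiro:
    def test_outlier_sample_is_not_normal(self):
        res = shapiro_normality([1, 1, 1, 1, 1, 1, 1, 100])
        assert res.is_normal is False
        assert res.p_value < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality([2.0, 2.0, 2.0, 2.0])

    def test_normal_draws_pass_most_of_the_time(self):
        """At alpha = 0.05, truly normal samples should be flagged
        normal in at least 94 of 100 seeded replicates."""
        rng = np.random.default_rng(7)
        hits = sum(
            shapiro_normality(rng.normal(size=500)).is_normal for _ in range(100)
        )
        assert hits >= 94


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], force="t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_extreme_separation_exact(self):
        """Fully separated ranks: U = 0 and the exact two-sided p is
        2 / C(6,3) = 0.1 (enumeration of all 20 rank assignments)."""
        res = compare_groups([1, 2, 3], [4, 5, 6], force="mann_whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_paired_all_zero_differences_degenerate(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.route == "degenerate"
        assert res.p_value == 1.0

    def test_length_mismatch_paired(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [1, 2, 3], paired=True)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            compare_groups([], [1, 2])

    def test_routing_records_route(self):
        rng = np.random.default_rng(3)
        res = compare_groups(rng.normal(size=20), rng.normal(size=20))
        assert res.route in ("normal", "nonnormal:exact", "nonnormal:asymptotic")

    def test_mann_whitney_exact_equals_enumeration(self):
        """Exact Mann-Whitney p equals brute-force enumeration over all
        C(n+m, n) group assignments, for a selection of small sizes
        (the full sweep over every pair <= 8 runs in the acceptance
        suite)."""
        from conftest import mwu_enumeration_p

        rng = np.random.default_rng(42)
        for n, m in [(2, 5), (3, 3), (4, 7), (5, 5), (8, 8)]:
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            res = compare_groups(a, b, force="mann_whitney")
            assert res.p_value == pytest.approx(mwu_enumeration_p(a, b), abs=1e-12), (n, m)


class TestChiSquared:
    def test_independence_gives_zero(self):
        res = chi_squared_proportions([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = chi_squared_proportions([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_proportions([[5, -1], [2, 3]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_proportions([[0, 0], [5, 5]])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        res = spearman_corr([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.statistic)
        assert res.route == "constant-input"

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_permutation_oracle(self, n):
        """The n <= 8 exact p equals a brute-force oracle that recomputes
        rho per permutation with scipy."""
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = spearman_corr(x, y)
        rho_obs = abs(sps.spearmanr(x, y).statistic)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            rho = abs(sps.spearmanr(x, np.asarray(y)[list(perm)]).statistic)
            count += rho >= rho_obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_exact_p_with_ties(self):
        """Mid-rank handling: ties in y still match the scipy-based
        permutation oracle."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.0, 1.0, 3.0, 3.0])
        res = spearman_corr(x, y)
        rho_obs = abs(sps.spearmanr(x, y).statistic)
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            rho = abs(sps.spearmanr(x, y[list(perm)]).statistic)
            hits += rho >= rho_obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)


class TestMatching:
    def test_simple_match(self):
        cases = pd.DataFrame({"id": ["c1"], "sex": ["F"], "age": [58]})
        controls = pd.DataFrame({"id": ["k1"], "sex": ["F"], "age": [57]})
        out = match_case_control(cases, controls)
        assert out.pairs == [("c1", "k1", ("F", 55))]
        assert out.unmatched_cases == []

    def test_sex_mismatch_leaves_unmatched(self):
        cases = pd.DataFrame({"id": ["c1"], "sex": ["F"], "age": [58]})
        controls = pd.DataFrame({"id": ["k1"], "sex": ["M"], "age": [58]})
        out = match_case_control(cases, controls)
        assert out.pairs == []
        assert out.unmatched_cases == ["c1"]

    def test_greedy_assignment_minimizes_within_stratum(self):
        cases = pd.DataFrame({"id": ["a", "b"], "sex": ["F", "F"], "age": [56, 59]})
        controls = pd.DataFrame({"id": ["x", "y"], "sex": ["F", "F"], "age": [55, 59]})
        out = match_case_control(cases, controls)
        got = {(c, k) for c, k, _ in out.pairs}
        assert got == {("b", "y"), ("a", "x")}

    def test_pairs_share_sex_and_band_property(self):
        rng = np.random.default_rng(5)
        cases = pd.DataFrame({
            "id": [f"c{i}" for i in range(30)],
            "sex": rng.choice(["M", "F"], 30),
            "age": rng.integers(40, 75, 30),
        })
        controls = pd.DataFrame({
            "id": [f"k{i}" for i in range(40)],
            "sex": rng.choice(["M", "F"], 40),
            "age": rng.integers(40, 75, 40),
        })
        out = match_case_control(cases, controls)
        case_lookup = cases.set_index("id")
        ctrl_lookup = controls.set_index("id")
        used = set()
        for c, k, (sex, band) in out.pairs:
            assert c not in used and k not in used
            used.update([c, k])
            assert case_lookup.loc[c, "sex"] == ctrl_lookup.loc[k, "sex"] == sex
            assert age_stratum(case_lookup.loc[c, "age"]) == band
            assert age_stratum(ctrl_lookup.loc[k, "age"]) == band

    def test_order_independent(self):
        rng = np.random.default_rng(9)
        cases = pd.DataFrame({
            "id": [f"c{i}" for i in range(12)],
            "sex": rng.choice(["M", "F"], 12),
            "age": rng.integers(40, 70, 12),
        })
        controls = pd.DataFrame({
            "id": [f"k{i}" for i in range(12)],
            "sex": rng.choice(["M", "F"], 12),
            "age": rng.integers(40, 70, 12),
        })
        a = match_case_control(cases, controls)
        b = match_case_control(
            cases.sample(frac=1, random_state=1), controls.sample(frac=1, random_state=2)
        )
        assert sorted(a.pairs) == sorted(b.pairs)


class TestPercentDifference:
    def test_reference_contrast(self):
        assert percent_difference(112.73, 141.39) == pytest.approx(25.4)
        assert percent_difference(1.22, 0.71) == pytest.approx(-41.8)

    def test_identity_zero(self):
        assert percent_difference(3.3, 3.3) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


class TestGroupTable:
    def test_single_subject_groups(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b"],
            "group": ["g1", "g2"],
            "joint": ["MCP2", "MCP2"],
            "jsw_mm": [1.5, 1.7],
            "ankylotic": [False, False],
        })
        out = assemble_group_table(df, value_cols=("jsw_mm",))
        row = out.iloc[0]
        assert row["g1_mean"] == 1.5 and row["g2_mean"] == 1.7
        assert row["g1_sd"] == 0.0

    def test_ankylotic_joint_excluded(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b"],
            "group": ["g1", "g1", "g2", "g2"],
            "joint": ["MCP2", "MCP3", "MCP2", "MCP3"],
            "jsw_mm": [1.5, 9.9, 1.7, 1.6],
            "ankylotic": [False, True, False, False],
        })
        out = assemble_group_table(df, value_cols=("jsw_mm",))
        mcp3 = out[out["joint"] == "MCP3"].iloc[0]
        assert mcp3["g1_n"] == 0

    def test_missing_grouping_column(self):
        with pytest.raises(ValueError):
            assemble_group_table(pd.DataFrame({"x": [1]}), grouping="group")


class TestCorrelationTable:
    def test_monotone_covariate_gives_rho_one(self):
        df = pd.DataFrame({
            "joint": ["MCP2"] * 6,
            "jsw_sd_mm": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            "time_since_diagnosis": [1, 3, 5, 8, 13, 21],
            "ankylotic": [False] * 6,
        })
        out = correlation_table(df, ("time_since_diagnosis",))
        assert len(out) == 1
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert out.iloc[0]["n"] == 6
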