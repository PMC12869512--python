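"""Gated comparison families: branch selection, oracles and error control."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from colonyprofiler import (
    StatConfig,
    blocked_anova_lsd,
    compare_sections_within_group,
    compare_treatments_vs_vehicle,
    dunn_test,
    paired_expression_test,
)


def sections_df(outer, middle, inner):
    rows = [("outer", v) for v in outer] + [("middle", v) for v in middle] + \
           [("inner", v) for v in inner]
    return pd.DataFrame(rows, columns=["section", "value"])


class TestWithinSections:
    def test_normal_data_takes_parametric_branch_with_tukey(self):
        rng = np.random.default_rng(0)
        df = sections_df(rng.normal(1.2, 0.1, 12), rng.normal(1.0, 0.1, 12),
                         rng.normal(0.8, 0.1, 12))
        res = compare_sections_within_group(df)
        assert res.branch == "parametric"
        assert res.omnibus_test == "one_way_anova"
        assert {frozenset((c.group_a, c.group_b)) for c in res.comparisons} == {
            frozenset(p) for p in (("outer", "middle"), ("outer", "inner"), ("middle", "inner"))
        }
        assert all(c.method == "tukey_hsd" for c in res.comparisons)

    def test_heavy_tailed_data_takes_nonparametric_branch(self):
        rng = np.random.default_rng(2)
        df = sections_df(rng.standard_cauchy(15), rng.standard_cauchy(15),
                         rng.standard_cauchy(15))
        res = compare_sections_within_group(df)
        assert res.branch == "nonparametric"
        assert res.omnibus_test == "kruskal_wallis"
        assert all(c.method == "dunn" for c in res.comparisons)

    def test_large_shift_detected_by_tukey(self):
        """Outer shifted +3 SD vs inner (n=10) flags that pair in >=95% of seeds."""
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            df = sections_df(rng.normal(3.0, 1.0, 10), rng.normal(1.5, 1.0, 10),
                             rng.normal(0.0, 1.0, 10))
            res = compare_sections_within_group(df)
            if res.comparison("outer", "inner").p < 0.05:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_missing_section_omitted_and_flagged(self):
        df = sections_df(np.random.default_rng(3).normal(1, 0.1, 10), [], [0.9] * 10)
        res = compare_sections_within_group(df)
        assert any(f.startswith("section_missing") or f.startswith("insufficient") or
                   "middle" in f for f in res.flags) or "middle" not in res.n_per_group

    def test_zero_variance_short_circuits(self):
        df = sections_df([1.0] * 5, [1.0] * 5, [1.0] * 5)
        res = compare_sections_within_group(df)
        assert res.branch == "none"
        assert "zero_variance" in res.flags

    def test_null_rejection_rate_near_alpha(self):
        """Omnibus type-I error stays within alpha +/- 0.02 under the null."""
        rng = np.random.default_rng(2024)
        n_sim, hits = 600, 0
        for _ in range(n_sim):
            df = sections_df(rng.normal(1, 0.1, 15), rng.normal(1, 0.1, 15),
                             rng.normal(1, 0.1, 15))
            if compare_sections_within_group(df).omnibus_p < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestVsVehicle:
    def _df(self, rng, shift=0.0):
        groups = {"vehicle": rng.normal(1, 0.1, 10), "lactate": rng.normal(1 + shift, 0.1, 10),
                  "oxamate": rng.normal(1, 0.1, 10), "azd": rng.normal(1, 0.1, 10)}
        return pd.DataFrame(
            [(t, v) for t, vs in groups.items() for v in vs], columns=["treatment", "value"]
        )

    def test_contrasts_only_against_vehicle(self):
        res = compare_treatments_vs_vehicle(self._df(np.random.default_rng(5)))
        assert len(res.comparisons) == 3
        assert all("vehicle" in (c.group_a, c.group_b) for c in res.comparisons)

    def test_null_rarely_significant(self):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            res = compare_treatments_vs_vehicle(self._df(np.random.default_rng(seed)))
            if any(c.p < 0.05 for c in res.comparisons):
                hits += 1
        assert hits / n_sim <= 0.10

    def test_shifted_treatment_detected_specifically(self):
        """A 2 SD shift in one treatment is flagged, and reliably only it."""
        correct = 0
        n_sim = 200
        for seed in range(n_sim):
            res = compare_treatments_vs_vehicle(self._df(np.random.default_rng(seed), shift=0.2))
            sig = {c.group_a for c in res.comparisons if c.p < 0.05}
            if sig == {"lactate"}:
                correct += 1
        assert correct / n_sim >= 0.80

    def test_missing_vehicle_raises(self):
        df = pd.DataFrame({"treatment": ["lactate"] * 5, "value": range(5)})
        with pytest.raises(ValueError, match="vehicle"):
            compare_treatments_vs_vehicle(df)

    def test_vehicle_only_input_raises(self):
        df = pd.DataFrame({"treatment": ["vehicle"] * 5, "value": np.arange(5.0)})
        with pytest.raises(ValueError, match="vehicle-only"):
            compare_treatments_vs_vehicle(df)

    def test_nonnormal_data_uses_dunn_on_vehicle_contrasts(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "treatment": ["vehicle"] * 12 + ["lactate"] * 12,
            "value": np.r_[rng.standard_cauchy(12), rng.standard_cauchy(12) + 5],
        })
        res = compare_treatments_vs_vehicle(df)
        assert res.branch == "nonparametric"
        assert all(c.method == "dunn" for c in res.comparisons)


class TestBlockedAnovaLSD:
    # RCBD with hand-computable sums of squares: 3 conditions x 3 blocks.
    #          b1  b2  b3      condition means: a=5, b=8, c=11 (grand 8)
    # a         4   5   6      block means: 7, 8, 9
    # b         7   8   9      SS_cond = 3*((5-8)^2+(8-8)^2+(11-8)^2) = 54
    # c        10  11  12      SS_block = 3*((7-8)^2+(8-8)^2+(9-8)^2) = 6
    #                          SS_total = 60 -> SS_err = 0 (perfectly additive)
    TABLE = pd.DataFrame({
        "response": [4, 5, 6, 7, 8, 9, 10, 11, 12],
        "condition": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        "block": ["b1", "b2", "b3"] * 3,
    })

    def test_hand_worked_rcbd_f_statistic(self):
        # perturb to get a non-degenerate error term, still hand-computable:
        # add 1 to cell (a, b1): recompute by the textbook decomposition below
        tab = self.TABLE.copy()
        tab.loc[0, "response"] = 5.0
        y = tab.pivot(index="condition", columns="block", values="response").to_numpy(float)
        grand = y.mean()
        ss_cond = 3 * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_block = 3 * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_block
        f_expected = (ss_cond / 2) / (ss_err / 4)
        res = blocked_anova_lsd(tab, "one_way")
        assert res.omnibus_stat == pytest.approx(f_expected, rel=1e-9)
        assert res.omnibus_p == pytest.approx(sps.f.sf(f_expected, 2, 4), rel=1e-9)

    def test_constant_conditions_give_null_result(self):
        tab = pd.DataFrame({
            "response": [1, 2, 3] * 3,
            "condition": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "block": ["b1", "b2", "b3"] * 3,
        })
        res = blocked_anova_lsd(tab, "one_way")
        assert res.omnibus_stat == pytest.approx(0.0, abs=1e-9)
        assert all(c.p == pytest.approx(1.0, abs=1e-9) for c in res.comparisons)

    def test_lsd_uses_preselected_pairs_only(self):
        res = blocked_anova_lsd(self.TABLE, "one_way", pairs=[("a", "c")])
        assert [(c.group_a, c.group_b) for c in res.comparisons] == [("a", "c")]
        assert all(c.method == "fisher_lsd" and c.p_adjusted is None for c in res.comparisons)

    def test_blocking_recovers_condition_effect_masked_by_block_noise(self):
        """With a huge block effect, the blocked design detects the condition
        while a plain one-way ANOVA on the same data does not."""
        rng = np.random.default_rng(7)
        conds, blocks = ["a", "b", "c"], [f"b{i}" for i in range(6)]
        cond_eff = {"a": 0.0, "b": 0.6, "c": 1.2}
        block_eff = {b: rng.normal(0, 10) for b in blocks}
        rows = [
            {"response": cond_eff[c] + block_eff[b] + rng.normal(0, 0.3),
             "condition": c, "block": b}
            for c in conds for b in blocks
        ]
        tab = pd.DataFrame(rows)
        blocked = blocked_anova_lsd(tab, "one_way")
        unblocked_p = sps.f_oneway(
            *[tab.loc[tab.condition == c, "response"] for c in conds]
        ).pvalue
        assert blocked.omnibus_p < 0.05 < unblocked_p

    def test_two_way_design_reports_factorial_table(self):
        rng = np.random.default_rng(9)
        rows = []
        for cell_type in ("naive", "primed"):
            for trt in ("vehicle", "lactate"):
                for b in ("b1", "b2", "b3"):
                    mu = 1.0 + (trt == "lactate") * 0.5 + (cell_type == "primed") * 0.3
                    rows.append({"response": mu + rng.normal(0, 0.1),
                                 "factor_a": cell_type, "factor_b": trt, "block": b})
        res = blocked_anova_lsd(pd.DataFrame(rows), "two_way",
                                pairs=[("naive:vehicle", "naive:lactate")])
        anova = res.extra["anova_table"]
        assert {"C(_fa)", "C(_fb)", "C(_fa):C(_fb)", "C(_block)", "Residual"} <= set(anova.index)
        assert res.comparisons[0].p < 0.05

    def test_condition_absent_everywhere_raises(self):
        tab = self.TABLE[self.TABLE.condition != "c"]
        with pytest.raises(ValueError, match="unknown condition"):
            blocked_anova_lsd(tab, "one_way", pairs=[("a", "c")])


class TestPairedExpression:
    def test_identical_pairs_give_p_one(self):
        res = paired_expression_test([1.0, 1.2, 0.9], [1.0, 1.2, 0.9])
        assert res.branch == "none"
        assert res.omnibus_p == 1.0
        assert "identical_pairs" in res.flags

    def test_matches_one_sample_t_on_log_ratios(self):
        logr = np.array([0.1, 0.12, 0.11])
        vehicle = np.ones(3)
        treated = np.exp(logr)
        res = paired_expression_test(vehicle, treated)
        # closed-form one-sample t
        t_expected = logr.mean() / (logr.std(ddof=1) / math.sqrt(3))
        p_expected = 2 * sps.t.sf(abs(t_expected), 2)
        assert res.branch == "parametric"
        assert res.omnibus_stat == pytest.approx(t_expected, rel=1e-12)
        assert res.omnibus_p == pytest.approx(p_expected, rel=1e-12)

    def test_skewed_ratios_take_wilcoxon_branch(self):
        rng = np.random.default_rng(3)
        vehicle = np.ones(12)
        treated = np.exp(np.r_[rng.normal(0, 0.01, 11), 5.0])  # one extreme outlier
        res = paired_expression_test(vehicle, treated)
        assert res.branch == "nonparametric"
        assert res.omnibus_test == "wilcoxon_matched_pairs"

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            paired_expression_test([1.0, 0.0], [1.0, 2.0])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(77)
        n_sim, hits = 800, 0
        for _ in range(n_sim):
            v = np.exp(rng.normal(0, 0.2, 9))
            t = v * np.exp(rng.normal(0, 0.2, 9))
            if paired_expression_test(v, t).omnibus_p < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestDunn:
    def test_matches_kruskal_on_two_groups_without_ties(self):
        """With two groups, Dunn's z^2 equals the Kruskal-Wallis H statistic."""
        rng = np.random.default_rng(13)
        groups = {"a": rng.normal(0, 1, 9), "b": rng.normal(1, 1, 11)}
        comp = dunn_test(groups, [("a", "b")])[0]
        h = sps.kruskal(groups["a"], groups["b"]).statistic
        assert comp.statistic**2 == pytest.approx(h, rel=1e-9)

    def test_bonferroni_option_scales_p(self):
        rng = np.random.default_rng(14)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        raw = dunn_test(groups, pairs)
        adj = dunn_test(groups, pairs, correction="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_adjusted == pytest.approx(min(1.0, r.p * 3))
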