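"""Flow Short Scale scoring and the quantitative analysis plan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import mann_whitney_exact_p, pooled_t
from glucoville.trial_stats import (DEFAULT_FSS_MAPPING, GroupSummary,
                                    TABLE2_SUMMARIES, cohens_d_from_summary,
                                    compare_groups, mann_whitney,
                                    reproduce_table2, sample_size_two_means,
                                    score_fss, synthesize_fss_responses,
                                    t_from_raw, t_from_summary,
                                    type_i_error_rate)

FLOW_CTRL = GroupSummary(26, 4.40, 0.89)
FLOW_INTV = GroupSummary(22, 4.95, 0.85)
ABS_CTRL = GroupSummary(26, 4.96, 0.83)
ABS_INTV = GroupSummary(22, 5.60, 0.87)


class TestScoreFSS:
    def test_all_sevens(self):
        s = score_fss([7] * 13)
        assert (s.fluency, s.absorption, s.importance, s.flow) == (7, 7, 7, 7)

    def test_all_ones(self):
        s = score_fss([1] * 13)
        assert (s.fluency, s.absorption, s.importance, s.flow) == (1, 1, 1, 1)

    def test_weighted_mean_identity_on_crafted_items(self):
        """Fluency items all 4 and absorption items all 6 give
        flow = (6*4 + 4*6)/10 = 4.8."""
        items = [0] * 13
        for i in DEFAULT_FSS_MAPPING["fluency"]:
            items[i - 1] = 4
        for i in DEFAULT_FSS_MAPPING["absorption"]:
            items[i - 1] = 6
        for i in DEFAULT_FSS_MAPPING["importance"]:
            items[i - 1] = 2
        s = score_fss(items)
        assert s.flow == pytest.approx(4.8)
        assert s.fluency == 4 and s.absorption == 6

    @given(st.lists(st.integers(1, 7), min_size=13, max_size=13))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_flow_equals_weighted_subscale_mean(self, items):
        s = score_fss(items)
        assert s.flow == pytest.approx((6 * s.fluency + 4 * s.absorption) / 10)

    @pytest.mark.parametrize("bad", [[4] * 12, [4] * 14, [0] + [4] * 12,
                                     [8] + [4] * 12, [4.5] + [4] * 12])
    def test_invalid_responses_rejected(self, bad):
        with pytest.raises(ValueError):
            score_fss(bad)

    def test_bad_mapping_rejected(self):
        bad = {"fluency": frozenset({1, 2, 3, 4, 5, 6}),
               "absorption": frozenset({7, 8, 9, 11}),  # leaks item 11
               "importance": frozenset({10, 12, 13})}
        with pytest.raises(ValueError):
            score_fss([4] * 13, mapping=bad)

    def test_printed_group_means_satisfy_flow_identity(self):
        """(6*fluency + 4*absorption)/10 reproduces the overall-flow group
        means from the subscale group means."""
        assert round((6 * 4.03 + 4 * 4.96) / 10, 2) == 4.40  # control
        assert round((6 * 4.52 + 4 * 5.60) / 10, 2) == 4.95  # intervention


class TestTTests:
    def test_overall_flow_summary_t(self):
        res = t_from_summary(FLOW_CTRL, FLOW_INTV, pooled=True)
        assert res.df == 46
        assert res.statistic == pytest.approx(-2.17, abs=0.01)
        assert res.p_two_sided == pytest.approx(0.04, abs=0.01)

    def test_absorption_summary_t(self):
        res = t_from_summary(ABS_CTRL, ABS_INTV, pooled=True)
        assert res.statistic == pytest.approx(-2.60, abs=0.005)
        assert res.p_two_sided == pytest.approx(0.01, abs=0.005)

    def test_identical_summaries_give_null_result(self):
        res = t_from_summary(FLOW_CTRL, FLOW_CTRL)
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_matches_hand_rolled_pooled_t(self, rng):
        x = rng.normal(5, 1, 26)
        y = rng.normal(4.5, 1.2, 22)
        res = t_from_raw(x, y)
        assert res.statistic == pytest.approx(pooled_t(x, y), rel=1e-12)

    def test_raw_equals_summary_to_1e12_relative(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.4, 1.5, 15)
            raw = t_from_raw(x, y)
            summ = t_from_summary(GroupSummary.from_raw(x),
                                  GroupSummary.from_raw(y))
            assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
            assert raw.p_two_sided == pytest.approx(summ.p_two_sided, rel=1e-12)

    def test_welch_equals_pooled_for_equal_n_equal_variance(self, rng):
        x = rng.normal(0, 1, 15)
        y = x + 0.7  # identical sample variance, equal n
        pooled = t_from_raw(x, y, pooled=True)
        welch = t_from_raw(x, y, pooled=False)
        assert welch.df == pytest.approx(pooled.df)
        assert welch.statistic == pytest.approx(pooled.statistic)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_from_raw([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            GroupSummary(1, 0.0, 1.0)


class TestCohensD:
    def test_overall_flow_effect_size(self):
        assert cohens_d_from_summary(FLOW_CTRL, FLOW_INTV) == \
            pytest.approx(0.63, abs=0.005)

    def test_absorption_effect_size(self):
        assert cohens_d_from_summary(ABS_CTRL, ABS_INTV) == \
            pytest.approx(0.75, abs=0.005)

    def test_equal_means_give_zero(self):
        assert cohens_d_from_summary(GroupSummary(10, 5.0, 1.0),
                                     GroupSummary(12, 5.0, 2.0)) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_summary(GroupSummary(10, 5.0, 0.0),
                                  GroupSummary(12, 4.0, 0.0))


class TestMannWhitney:
    def test_complete_separation_gives_u_zero(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_samples_give_u_half_n_squared(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == 16 / 2

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (3, 4), (4, 4),
                                       (2, 5), (5, 5), (4, 6)])
    def test_p_matches_exhaustive_enumeration(self, na, nb, rng):
        """Exact p agrees with brute-force enumeration over all
        C(na+nb, na) labelings, for tie-free samples of combined n <= 10."""
        for _ in range(3):
            pool = rng.permutation(np.arange(1.0, na + nb + 1))
            x, y = pool[:na], pool[na:]
            res = mann_whitney(x, y)
            assert res.p_two_sided == pytest.approx(
                mann_whitney_exact_p(x, y), abs=1e-9)


class TestSampleSize:
    def test_trial_power_inputs_give_twenty_per_group(self):
        """alpha 5%, power 90%, means 4 vs 5.05, SD 1: the closed-form
        normal approximation gives ceil(2*(z.975+z.90)^2/1.05^2) = 20."""
        res = sample_size_two_means(0.05, 0.90, 4.0, 5.05, 1.0)
        assert res.normal_approx == 20
        assert res.power_at_n >= 0.90
        assert abs(res.per_group - res.normal_approx) <= 1

    def test_doubling_sd_quadruples_n(self):
        n1 = sample_size_two_means(0.05, 0.90, 4.0, 5.05, 1.0).normal_approx
        n2 = sample_size_two_means(0.05, 0.90, 4.0, 5.05, 2.0).normal_approx
        assert 4 * n1 - 3 <= n2 <= 4 * n1

    def test_half_power_at_delta_equal_sd(self):
        res = sample_size_two_means(0.05, 0.50, 0.0, 1.0, 1.0)
        assert res.normal_approx == 8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_means(0.0, 0.9, 4.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            sample_size_two_means(0.05, 0.9, 4.0, 4.0, 1.0)


class TestAnalysisPlan:
    def test_normal_data_gets_t_test_with_effect_size(self, rng):
        x = rng.normal(5, 1, 26)
        y = rng.normal(4.5, 1, 22)
        res = compare_groups(x, y)
        assert res.method.startswith("t_")
        assert res.effect_size is not None and res.effect_size >= 0

    def test_skewed_data_falls_back_to_mann_whitney(self, rng):
        x = rng.exponential(1.0, 40) ** 2
        y = rng.exponential(1.5, 40) ** 2
        res = compare_groups(x, y)
        assert res.method.startswith("mann_whitney")

    def test_unequal_variances_trigger_welch(self, rng):
        x = rng.normal(0, 0.3, 40)
        y = rng.normal(0, 3.0, 40)
        res = compare_groups(x, y)
        assert res.method in ("t_welch", "mann_whitney_asymptotic")

    def test_type_i_error_quick_calibration(self, rng):
        rate = type_i_error_rate(26, 22, 0.05, 4000, rng)
        assert 0.03 <= rate <= 0.07


class TestTable2Reproduction:
    def test_all_rows_have_df_46(self):
        df = reproduce_table2()
        assert (df.df == 46).all()
        assert len(df) == 7

    def test_synthetic_fss_path_end_to_end(self, rng):
        """Latent-flow generator -> item scoring -> analysis plan runs and
        recovers a positive arm difference when one is simulated."""
        lo = synthesize_fss_responses(26, 4.0, rng)
        hi = synthesize_fss_responses(22, 5.2, rng)
        flow_lo = [score_fss(list(r)).flow for r in lo]
        flow_hi = [score_fss(list(r)).flow for r in hi]
        res = compare_groups(flow_lo, flow_hi)
        assert res.statistic < 0  # control below intervention
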