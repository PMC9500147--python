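"""Mixed-design ANOVA, Bonferroni post hocs, reliability and sample size."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abpsurge.inference import (
    bonferroni_posthoc,
    icc_day_to_day,
    mixed_anova,
    sample_size_two_group,
    validate_cohort_table,
)

from conftest import anova_fixture_data, long_table_from_array, split_plot_oracle


class TestMixedAnova:
    def test_matches_projection_oracle_to_six_sig_figs(self):
        data = anova_fixture_data(seed=42)
        res = mixed_anova(long_table_from_array(data), "mean_24h_sbp")
        oracle = split_plot_oracle(data)
        for name in ("F_group", "F_time", "F_interaction",
                     "p_group", "p_time", "p_interaction"):
            assert getattr(res, name) == pytest.approx(oracle[name], rel=1e-6)
        assert res.df_group == (1, 6)
        assert res.df_time == (2, 12)
        assert res.df_interaction == (2, 12)

    def test_all_identical_values_give_zero_f(self):
        data = np.full((2, 4, 3), 117.0)
        res = mixed_anova(long_table_from_array(data), "mean_24h_sbp")
        assert res.F_time == 0.0
        assert res.F_interaction == 0.0

    def test_location_invariance(self):
        data = anova_fixture_data(seed=3)
        r1 = mixed_anova(long_table_from_array(data), "mean_24h_sbp")
        r2 = mixed_anova(long_table_from_array(data + 250.0), "mean_24h_sbp")
        assert r1.F_time == pytest.approx(r2.F_time, rel=1e-9)
        assert r1.F_group == pytest.approx(r2.F_group, rel=1e-7)
        assert r1.F_interaction == pytest.approx(r2.F_interaction, rel=1e-9)

    def test_single_group_collapses_to_one_way_rm(self):
        data = anova_fixture_data(seed=8)[:1]  # one group, 4 subjects
        res = mixed_anova(long_table_from_array(data), "mean_24h_sbp")
        # one-way repeated-measures oracle via direct sums of squares
        x = data[0]
        n, t_n = x.shape
        mu = x.mean()
        ss_time = n * ((x.mean(0) - mu) ** 2).sum()
        ss_subj = t_n * ((x.mean(1) - mu) ** 2).sum()
        ss_resid = ((x - mu) ** 2).sum() - ss_time - ss_subj
        f_time = (ss_time / (t_n - 1)) / (ss_resid / ((n - 1) * (t_n - 1)))
        assert res.F_time == pytest.approx(f_time, rel=1e-9)
        assert np.isnan(res.F_group)

    def test_incomplete_subject_errors(self):
        table = long_table_from_array(anova_fixture_data(seed=1))
        table = table[~((table.subject_id == "G0S00") & (table.timepoint == "mid"))]
        with pytest.raises(ValueError, match="listwise"):
            mixed_anova(table, "mean_24h_sbp")

    def test_duplicate_rows_rejected(self):
        table = long_table_from_array(anova_fixture_data(seed=1))
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort_table(pd.concat([table, table.iloc[:1]]))


class TestBonferroniPosthoc:
    def within(self, comps, group, pair):
        return next(
            c for c in comps
            if c.scope == "within" and c.group == group and c.pair == pair
        )

    def test_identical_pre_post_gives_null_comparison(self):
        data = anova_fixture_data(seed=4, effect=0.0)
        data[:, :, 1] = data[:, :, 0]  # mid == baseline exactly
        comps = bonferroni_posthoc(long_table_from_array(data), "mean_24h_sbp")
        c = self.within(comps, "G0", ("baseline", "mid"))
        assert c.estimate == 0.0
        assert c.p_adjusted == 1.0

    def test_cap_at_one(self):
        rng = np.random.default_rng(0)
        data = 120 + rng.standard_normal((2, 6, 3))
        comps = bonferroni_posthoc(long_table_from_array(data), "mean_24h_sbp")
        for c in comps:
            m = 3
            assert c.p_adjusted == pytest.approx(min(1.0, m * c.p_raw))
        assert any(c.p_adjusted == 1.0 for c in comps)

    def test_programmed_shift_recovered(self):
        # -8 mmHg mid-vs-baseline in group 0; oracle: hand paired t test
        data = anova_fixture_data(seed=10, n=8, effect=-8.0)
        comps = bonferroni_posthoc(long_table_from_array(data), "mean_24h_sbp")
        c = self.within(comps, "G0", ("baseline", "mid"))
        d = data[0, :, 1] - data[0, :, 0]
        t_hand, p_hand = stats.ttest_rel(data[0, :, 1], data[0, :, 0])
        assert c.estimate == pytest.approx(d.mean())
        assert abs(c.estimate + 8.0) < 3 * d.std(ddof=1) / np.sqrt(len(d))
        assert c.t == pytest.approx(t_hand)
        assert c.p_adjusted == pytest.approx(min(1.0, 3 * p_hand))
        assert c.p_adjusted < 0.05

    def test_between_group_sign_convention(self):
        data = anova_fixture_data(seed=6, effect=0.0)
        data[0] += 10.0  # first group higher everywhere
        comps = bonferroni_posthoc(long_table_from_array(data), "mean_24h_sbp")
        between = [c for c in comps if c.scope == "between"]
        assert len(between) == 3
        for c in between:
            assert c.pair == ("G0", "G1")
            assert c.estimate > 0

    def test_zero_variance_nonzero_diff_errors(self):
        data = anova_fixture_data(seed=5, effect=0.0)
        data[0, :, 1] = data[0, :, 0] + 4.0  # constant nonzero difference
        with pytest.raises(ValueError, match="zero variance"):
            bonferroni_posthoc(long_table_from_array(data), "mean_24h_sbp")


class TestICC:
    def test_perfect_agreement(self):
        r = icc_day_to_day([100, 110, 120, 130], [100, 110, 120, 130])
        assert r.icc == 1.0
        assert r.cv_pct == 0.0

    def test_rms_difference_example(self):
        # d = (-2, 0): sd_w = sqrt(4/4) = 1.0; grand mean 99.5
        r = icc_day_to_day([100, 98, 100], [102, 98, 100])
        # extend the two-pair example with an identical third pair keeps sd_w
        d = np.array([-2.0, 0.0, 0.0])
        sd_w = np.sqrt((d**2).sum() / (2 * 3))
        assert r.cv_pct == pytest.approx(100 * sd_w / np.mean([100, 98, 100, 102, 98, 100]))

    def test_matches_mean_squares_oracle(self):
        rng = np.random.default_rng(12)
        x = 120 + 6 * rng.standard_normal(15)
        y = x + 2.5 * rng.standard_normal(15) + 1.0
        r = icc_day_to_day(x, y)
        # ICC(2,1) from the two-way mean squares
        n, k = 15, 2
        mat = np.column_stack([x, y])
        grand = mat.mean()
        msr = k * ((mat.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((mat.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((mat - mat.mean(1, keepdims=True) - mat.mean(0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        icc_hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert r.icc == pytest.approx(icc_hand, rel=1e-6)

    def test_permutation_destroys_agreement(self):
        rng = np.random.default_rng(21)
        x = 120 + 6 * rng.standard_normal(300)
        y = x + rng.standard_normal(300)
        assert icc_day_to_day(x, y).icc > 0.9
        assert abs(icc_day_to_day(x, rng.permutation(y)).icc) < 0.15

    def test_translation_moves_cv_not_icc(self):
        rng = np.random.default_rng(5)
        x = 120 + 5 * rng.standard_normal(12)
        y = x + 2 * rng.standard_normal(12)
        r1, r2 = icc_day_to_day(x, y), icc_day_to_day(x + 100, y + 100)
        assert r1.icc == pytest.approx(r2.icc, rel=1e-9)
        assert r2.cv_pct < r1.cv_pct

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            icc_day_to_day([1.0, 2.0], [1.0, 2.0])


class TestSampleSize:
    def test_reference_effect_size_gives_total_twenty(self):
        res = sample_size_two_group(d=1.33, alpha=0.05, power=0.80)
        assert res.n_per_group == 10
        assert res.n_total == 20
        assert res.achieved_power >= 0.80

    def test_medium_effect(self):
        # oracle: noncentral-t power iteration (independently verified with
        # statsmodels below)
        assert sample_size_two_group(d=0.5).n_per_group == 64

    def test_huge_effect_floors_at_two(self):
        assert sample_size_two_group(d=10.0).n_per_group == 2

    def test_minimality_and_monotonicity(self):
        from abpsurge.inference import _power_two_sample

        res = sample_size_two_group(d=0.8)
        assert _power_two_sample(res.n_per_group - 1, 0.8, 0.05) < 0.80
        powers = [_power_two_sample(n, 0.8, 0.05) for n in range(2, 60)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.4, 0.9, 1.33):
            ours = sample_size_two_group(d=d).n_per_group
            theirs = TTestIndPower().solve_power(
                effect_size=d, alpha=0.05, power=0.80, alternative="two-sided"
            )
            assert ours == int(np.ceil(theirs))

    def test_attrition_inflates_recruitment(self):
        res = sample_size_two_group(d=1.33, attrition=0.20)
        assert res.n_recruit == 25

    @pytest.mark.parametrize(
        "kwargs", [dict(d=-1.0), dict(d=0.5, alpha=0.0), dict(d=0.5, power=1.0),
                   dict(d=0.5, attrition=1.0)]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            sample_size_two_group(**kwargs)
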