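"""Log10 intensity transform, ANOVA (raw and from summaries), Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pepdiff.intensity as it

from conftest import make_candidates


def obs_frame(values, groups):
    return pd.DataFrame({"entity": "G", "treatment_id": groups,
                         "patient_id": "p", "log10_intensity": values})


def direct_anova(values, groups):
    """Independent SS decomposition from the definitions."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_t = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
               for g in np.unique(groups))
    return ss_t, ss_total - ss_t


class TestLog10Transform:
    def test_known_values(self):
        df = make_candidates([
            {"spectrum_id": "a", "precursor_intensity": 10_000.0},
            {"spectrum_id": "b", "precursor_intensity": 1e6},
        ])
        obs = it.log10_transform(df)
        np.testing.assert_allclose(obs["log10_intensity"], [4.0, 6.0])
        assert obs["treatment_id"].tolist() == [5, 5]

    def test_matches_independent_log(self, rng):
        vals = 10 ** rng.uniform(4, 8, size=100)
        df = make_candidates([{"spectrum_id": f"S{i}",
                               "precursor_intensity": float(v)}
                              for i, v in enumerate(vals)])
        obs = it.log10_transform(df)
        np.testing.assert_allclose(obs["log10_intensity"],
                                   [np.log10(v) for v in vals], rtol=1e-12)


class TestNormalityCheck:
    def test_normal_data_passes(self, rng):
        reps = 0
        for k in range(100):
            x = np.random.default_rng(k).normal(5, 0.5, size=200)
            out = it.normality_check(obs_frame(x, 5))
            reps += out.iloc[0]["p"] > 0.01
        assert reps >= 95

    def test_lognormal_raw_fails_log_passes(self):
        raw = np.random.default_rng(11).lognormal(mean=np.log(10 ** 4.6),
                                                  sigma=1.2, size=300)
        p_raw = it.normality_check(obs_frame(raw, 5)).iloc[0]["p"]
        p_log = it.normality_check(obs_frame(np.log10(raw), 5)).iloc[0]["p"]
        assert p_raw < 0.01 < p_log

    def test_degenerate_group_skipped(self):
        out = it.normality_check(obs_frame([4.0] * 10, 5))
        assert out.iloc[0]["skipped"]
        tiny = it.normality_check(obs_frame([4.0, 4.1], 5))
        assert tiny.iloc[0]["skipped"]


class TestOneWayAnova:
    def test_hand_example(self):
        res = it.one_way_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(res.ss_treatment, 1.5)
        np.testing.assert_allclose(res.ss_residual, 4.0)
        assert (res.df_treatment, res.df_residual) == (1, 4)
        np.testing.assert_allclose(res.f_value, 1.5)

    def test_equal_groups_give_zero_between_ss(self):
        res = it.one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(res.ss_treatment, 0, atol=1e-12)

    def test_shift_and_scale_invariance_of_f(self, rng):
        y = rng.normal(5, 1, size=40)
        g = rng.choice(["a", "b", "c"], size=40)
        base = it.one_way_anova(y, g)
        shifted = it.one_way_anova(3.0 * y + 11.0, g)
        np.testing.assert_allclose(shifted.f_value, base.f_value, rtol=1e-9)
        np.testing.assert_allclose(shifted.p_value, base.p_value, rtol=1e-9)

    def test_ss_conservation(self, rng):
        y = rng.normal(size=60)
        g = rng.choice(list("abcd"), size=60)
        res = it.one_way_anova(y, g)
        ss_total = ((y - y.mean()) ** 2).sum()
        np.testing.assert_allclose(res.ss_treatment + res.ss_residual,
                                   ss_total, rtol=1e-9)

    def test_identical_values_degenerate(self):
        with pytest.raises(it.DegenerateDataError):
            it.one_way_anova([2.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestAnovaFromSummary:
    def test_matches_raw_hand_example(self):
        res = it.anova_from_summary([2, 3], [1, 1], [3, 3])
        np.testing.assert_allclose(res.f_value, 1.5)
        np.testing.assert_allclose(res.ss_treatment, 1.5)
        np.testing.assert_allclose(res.ss_residual, 4.0)

    def test_duplicated_group_zero_between(self):
        res = it.anova_from_summary([3, 3], [1, 1], [5, 5])
        np.testing.assert_allclose(res.ss_treatment, 0, atol=1e-12)

    def test_sd_missing_with_n2_is_error(self):
        with pytest.raises(ValueError):
            it.anova_from_summary([1, 2], [np.nan, 1.0], [3, 3])

    def test_sd_optional_for_singletons(self):
        res = it.anova_from_summary([1, 2, 3], [np.nan, 1.0, 1.0], [1, 4, 4])
        assert res.df_residual == 6

    def test_equivalence_with_raw_anova(self, rng):
        for _ in range(20):
            k = rng.integers(2, 8)
            ns = rng.integers(2, 12, size=k)
            y = [rng.normal(rng.normal(5, 1), 1, size=n) for n in ns]
            groups = np.repeat(np.arange(k), ns)
            raw = it.one_way_anova(np.concatenate(y), groups)
            summ = it.anova_from_summary([v.mean() for v in y],
                                         [v.std(ddof=1) for v in y], ns)
            np.testing.assert_allclose(summ.ss_treatment, raw.ss_treatment,
                                       rtol=1e-9)
            np.testing.assert_allclose(summ.ss_residual, raw.ss_residual,
                                       rtol=1e-9)
            np.testing.assert_allclose(summ.f_value, raw.f_value, rtol=1e-9)
            np.testing.assert_allclose(summ.p_value, raw.p_value, rtol=1e-9)
            assert (summ.df_treatment, summ.df_residual) == \
                   (raw.df_treatment, raw.df_residual)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        ns = rng.integers(2, 9, size=k)
        y = np.concatenate([rng.normal(m, 1, size=n)
                            for m, n in zip(rng.normal(0, 2, k), ns)])
        g = np.repeat(np.arange(k), ns)
        if np.ptp(y) == 0:
            return
        raw = it.one_way_anova(y, g)
        means = [y[g == i].mean() for i in range(k)]
        sds = [y[g == i].std(ddof=1) for i in range(k)]
        summ = it.anova_from_summary(means, sds, ns)
        np.testing.assert_allclose(summ.f_value, raw.f_value, rtol=1e-9)


class TestTwoWayAnova:
    def test_balanced_2x2_additive(self):
        # y = t_effect + p_effect on a balanced design, duplicated cells
        t = np.array(["t1", "t1", "t2", "t2"] * 2)
        p = np.array(["p1", "p2", "p1", "p2"] * 2)
        eff_t = np.where(t == "t2", 2.0, 0.0)
        eff_p = np.where(p == "p2", 1.0, 0.0)
        # noise orthogonal to both factors leaves the marginal SS exact
        y = 4.0 + eff_t + eff_p + np.array([0.1, -0.1, -0.1, 0.1] * 2)
        tab = it.two_way_anova(y, t, p)
        np.testing.assert_allclose(tab.loc["treatment", "Sum Sq"], 8.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(tab.loc["peptide", "Sum Sq"], 2.0,
                                   rtol=1e-9)

    def test_constant_peptide_collapses_to_one_way(self):
        y = [1, 2, 3, 2, 3, 4]
        t = ["a"] * 3 + ["b"] * 3
        with pytest.warns(UserWarning, match="constant"):
            tab = it.two_way_anova(y, t, ["p1"] * 6)
        one = it.one_way_anova(y, t)
        np.testing.assert_allclose(tab.loc["treatment", "Sum Sq"],
                                   one.ss_treatment, rtol=1e-9)
        assert tab.loc["peptide", "Sum Sq"] == 0.0
        np.testing.assert_allclose(tab.loc["residuals", "Sum Sq"],
                                   one.ss_residual, rtol=1e-9)

    def test_permutation_invariance(self, rng):
        n = 60
        y = rng.normal(size=n)
        t = rng.choice(["a", "b", "c"], size=n)
        p = rng.choice(["x", "y"], size=n)
        tab = it.two_way_anova(y, t, p)
        perm = rng.permutation(n)
        tab2 = it.two_way_anova(y[perm], t[perm], p[perm])
        pd.testing.assert_frame_equal(tab, tab2)

    def test_two_treatment_levels_required(self):
        with pytest.raises(ValueError):
            it.two_way_anova([1, 2, 3], ["a", "a", "a"], ["x", "y", "x"])


class TestTukeyKramer:
    def test_identical_groups_share_a_letter(self):
        summ = pd.DataFrame({"treatment_id": [1, 2], "mean": [5.0, 5.0],
                             "n": [10, 10]})
        res = it.tukey_kramer(summ, ms_residual=1.0, df_residual=18)
        assert set(res.letters[1]) & set(res.letters[2])

    def test_separated_groups_get_distinct_letters(self):
        summ = pd.DataFrame({"treatment_id": [1, 2], "mean": [10.0, 20.0],
                             "n": [10, 10]})
        res = it.tukey_kramer(summ, ms_residual=1.0, df_residual=18)
        assert not (set(res.letters[1]) & set(res.letters[2]))
        # oracle: the pairwise statistic against the studentized-range quantile
        se = np.sqrt((1.0 / 2) * (1 / 10 + 1 / 10))
        stat = 10.0 / se
        assert stat > stats.studentized_range.ppf(0.95, 2, 18)

    def test_letter_relation_complements_significance(self, rng):
        k = 7
        summ = pd.DataFrame({"treatment_id": np.arange(k),
                             "mean": rng.normal(5, 0.6, size=k),
                             "n": rng.integers(4, 30, size=k)})
        res = it.tukey_kramer(summ, ms_residual=0.3, df_residual=120)
        q_crit = stats.studentized_range.ppf(0.95, k, 120)
        for _, row in res.pairwise.iterrows():
            i, j = row["group_1"], row["group_2"]
            shares = bool(set(res.letters[i]) & set(res.letters[j]))
            ni = summ.set_index("treatment_id").loc[i, "n"]
            nj = summ.set_index("treatment_id").loc[j, "n"]
            mi = summ.set_index("treatment_id").loc[i, "mean"]
            mj = summ.set_index("treatment_id").loc[j, "mean"]
            stat = abs(mi - mj) / np.sqrt((0.3 / 2) * (1 / ni + 1 / nj))
            assert shares == (stat <= q_crit)

    def test_matches_statsmodels_on_raw_data(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        y = np.concatenate([rng.normal(m, 1, size=15) for m in (0, 0.5, 3)])
        g = np.repeat(["a", "b", "c"], 15)
        aov = it.one_way_anova(y, g)
        summ = pd.DataFrame({
            "treatment_id": ["a", "b", "c"],
            "mean": [y[g == x].mean() for x in "abc"],
            "n": [15, 15, 15]})
        mine = it.tukey_kramer(summ, aov.ms_residual, aov.df_residual)
        ref = pairwise_tukeyhsd(y, g, alpha=0.05)
        from itertools import combinations
        ref_sig = {frozenset(pair): rej for pair, rej in
                   zip(combinations(sorted(set(g)), 2), ref.reject)}
        for _, row in mine.pairwise.iterrows():
            key = frozenset((row["group_1"], row["group_2"]))
            assert row["significant"] == ref_sig[key]

    def test_df_residual_validation(self):
        summ = pd.DataFrame({"treatment_id": [1, 2], "mean": [1.0, 2.0],
                             "n": [3, 3]})
        with pytest.raises(ValueError):
            it.tukey_kramer(summ, 1.0, 0)


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        out = it.compact_letter_display([1, 2, 3], [])
        assert len({out[g] for g in out}) == 1

    def test_all_different_all_distinct(self):
        out = it.compact_letter_display(
            [1, 2, 3], [(1, 2), (1, 3), (2, 3)])
        letters = [set(out[g]) for g in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not letters[i] & letters[j]

    def test_chain_structure(self):
        # 1 differs from 3 only: 2 bridges both
        out = it.compact_letter_display([1, 2, 3], [(1, 3)])
        assert set(out[1]) & set(out[2])
        assert set(out[2]) & set(out[3])
        assert not set(out[1]) & set(out[3])


class TestSummarizeEntityAndModel:
    def make_obs(self, rng):
        rows = []
        for tid, mu, n in ((5, 5.9, 25), (9, 4.5, 40), (7, 4.8, 12)):
            for v in rng.normal(mu, 0.5, size=n):
                rows.append({"entity": "G", "treatment_id": tid,
                             "patient_id": "p", "log10_intensity": v})
        return pd.DataFrame(rows)

    def test_summaries_match_brute_force(self, rng):
        obs = self.make_obs(rng)
        summ = it.summarize_entity(obs, "G")
        for _, row in summ.iterrows():
            vals = obs.loc[obs["treatment_id"] == row["treatment_id"],
                           "log10_intensity"]
            np.testing.assert_allclose(row["mean"], vals.mean())
            np.testing.assert_allclose(row["sd"], vals.std(ddof=1))
            assert row["n"] == len(vals)

    def test_round_trip_summary_equals_raw_anova(self, rng):
        obs = self.make_obs(rng)
        summ = it.summarize_entity(obs, "G")
        from_raw = it.one_way_anova(obs["log10_intensity"],
                                    obs["treatment_id"])
        from_summ = it.anova_from_summary(summ["mean"], summ["sd"], summ["n"])
        np.testing.assert_allclose(from_summ.f_value, from_raw.f_value,
                                   rtol=1e-9)
        np.testing.assert_allclose(from_summ.ss_residual, from_raw.ss_residual,
                                   rtol=1e-9)

    def test_single_treatment_entity_has_no_letters(self, rng):
        obs = pd.DataFrame({"entity": "G", "treatment_id": 5, "patient_id": "p",
                            "log10_intensity": rng.normal(5, 0.3, size=8)})
        summ = it.summarize_entity(obs, "G")
        assert len(summ) == 1
        assert summ.iloc[0]["letters"] == ""

    def test_model_fit_from_observations(self, rng):
        obs = self.make_obs(rng)
        res = it.IntensityAnova(observations=obs, entity="G").fit()
        assert res.anova.df_treatment == 2
        assert set(res.groups["treatment_id"]) == {5, 7, 9}
        assert "One-way ANOVA" in res.summary()

    def test_model_requires_exactly_one_input(self, rng):
        with pytest.raises(ValueError):
            it.IntensityAnova()

    def test_sd_zero_groups_participate(self):
        summ = pd.DataFrame({"treatment_id": [1, 2, 3],
                             "mean": [4.0, 4.1, 5.0],
                             "sd": [0.0, 0.4, 0.4], "n": [4, 20, 20]})
        res = it.IntensityAnova.from_summary(summ).fit()
        assert res.anova.df_residual == 41
        assert res.groups["letters"].str.len().gt(0).all()
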