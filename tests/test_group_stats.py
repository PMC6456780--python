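"""Statistical battery: ANOVAs, summary-statistic forms, post-hocs, U test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmnstudy.group_stats import (SummaryStats, anova_from_summary,
                                  anova_oneway, bonferroni_pairwise,
                                  mann_whitney, rm_anova, run_study,
                                  t_from_summary, tukey_hsd)


def _moments(values_by_group):
    return [SummaryStats(g, float(np.mean(v)), float(np.std(v, ddof=1)),
                         len(v)) for g, v in values_by_group.items()]


def _brute_force_oneway(groups):
    """SS decomposition from first principles."""
    all_v = np.concatenate(list(groups.values()))
    grand = all_v.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
              for v in groups.values())
    k, N = len(groups), len(all_v)
    return (ssb / (k - 1)) / (ssw / (N - k))


def _brute_force_rm(x):
    n, c = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(c))
    ss_err = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(c))
    return (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (n - 1)))


def _brute_force_u(a, b):
    u_a = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return min(u_a, len(a) * len(b) - u_a)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in "abc"}
        assert anova_oneway(g).F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        res = anova_oneway({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t ** 2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i * 0.3, 1 + i * 0.2,
                                      rng.integers(3, 12))
                  for i in range(rng.integers(2, 5))}
        res = anova_oneway(groups)
        assert res.F == pytest.approx(_brute_force_oneway(groups), rel=1e-10)
        assert res.df_between == len(groups) - 1
        assert res.df_within == sum(map(len, groups.values())) - len(groups)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": np.ones(5)})
        with pytest.raises(ValueError):
            anova_oneway({"a": np.ones(5), "b": np.ones(5)})


class TestSummaryForms:
    @pytest.mark.parametrize("means,sds,expected_F", [
        # published demographic worked examples (n = 20 per group)
        ((40.05, 44.35, 42.35), (11.55, 11.49, 11.31), 0.70),
        ((19.00, 18.25, 17.00), (12.73, 11.61, 7.32), 0.17),
    ])
    def test_published_anova_rows(self, means, sds, expected_F):
        res = anova_from_summary(
            [SummaryStats(str(i), m, s, 20)
             for i, (m, s) in enumerate(zip(means, sds))])
        assert res.df_between == 2 and res.df_within == 57
        assert res.F == pytest.approx(expected_F, abs=0.005 + 0.02 * expected_F)

    def test_published_t_row(self):
        """The tinnitus-handicap-inventory severity contrast."""
        res = t_from_summary(SummaryStats("comp", 19.60, 5.93, 20),
                             SummaryStats("decomp", 74.90, 11.81, 20))
        assert res["t"] == pytest.approx(-18.70, rel=0.02)
        assert res["df"] == 38

    def test_equal_means_f_zero(self):
        res = anova_from_summary([SummaryStats("a", 5, 1, 10),
                                  SummaryStats("b", 5, 2, 10)])
        assert res.F == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_summary_equals_raw_anova(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i, 1, rng.integers(5, 15))
                  for i in range(3)}
        raw = anova_oneway(groups)
        summ = anova_from_summary(_moments(groups))
        assert summ.F == pytest.approx(raw.F, rel=1e-10)
        assert summ.p == pytest.approx(raw.p, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_summary_t_equals_raw_t(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 14), rng.normal(0.5, 1.3, 9)
        res = t_from_summary(*_moments({"a": a, "b": b}))
        t, p = stats.ttest_ind(a, b)
        assert res["t"] == pytest.approx(t, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)

    def test_identical_groups_t_zero(self):
        res = t_from_summary(SummaryStats("a", 3, 1, 10),
                             SummaryStats("b", 3, 1, 10))
        assert res["t"] == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            SummaryStats("a", 0.0, -1.0, 10)
        with pytest.raises(ValueError):
            SummaryStats("a", 0.0, 1.0, 1)
        with pytest.raises(ValueError):
            t_from_summary(SummaryStats("a", 1, 0, 5),
                           SummaryStats("b", 1, 0, 5))


class TestTukey:
    def test_separated_group_detected(self):
        rng = np.random.default_rng(2)
        groups = {"g1": rng.normal(0, 1, 20), "g2": rng.normal(0, 1, 20),
                  "g3": rng.normal(10, 1, 20)}
        res = {r.pair: r.p_adjusted for r in tukey_hsd(groups)}
        assert res[("g1", "g3")] < 0.01
        assert res[("g1", "g2")] > 0.05

    def test_identical_groups_p_near_one(self):
        g = {k: np.array([1.0, 2.0, 3.0, 4.0]) for k in "abc"}
        assert all(r.p_adjusted > 0.99 for r in tukey_hsd(g))

    @pytest.mark.parametrize("seed", range(10))
    def test_adjusted_p_dominates_pairwise_t(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(0, 1, 12) for i in range(3)}
        tuk = {r.pair: r.p_adjusted for r in tukey_hsd(groups)}
        for (ga, gb), p_adj in tuk.items():
            _, p_raw = stats.ttest_ind(groups[ga], groups[gb])
            assert p_adj >= p_raw - 1e-12


class TestRMAnova:
    def test_study_design_dfs(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.normal(0, 1, (20, 4)))
        assert res.df_effect == 3 and res.df_error == 57

    def test_identical_conditions_f_zero(self):
        x = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        assert rm_anova(x).F == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (6, 3))
        assert rm_anova(x).F == pytest.approx(_brute_force_rm(x), rel=1e-10)

    def test_matches_pingouin(self):
        """Independent cross-check against an established implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (12, 4))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": x.ravel(),
        })
        pg = pingouin.rm_anova(data=df, dv="y", within="cond",
                               subject="subject", correction=False)
        res = rm_anova(x)
        assert res.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(pg["p_unc"].iloc[0]), rel=1e-6)

    def test_gg_correction_shrinks_df(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (10, 4))
        x[:, 0] *= 4.0  # break sphericity
        res = rm_anova(x, gg_correction=True)
        assert res.epsilon < 1.0
        assert res.df_effect < 3

    def test_missing_cells_raise(self):
        x = np.ones((5, 3))
        x[2, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova(x)


class TestBonferroni:
    def test_four_conditions_six_pairs(self):
        res = bonferroni_pairwise(np.random.default_rng(0).normal(0, 1, (8, 4)))
        assert len(res) == 6

    def test_adjustment_definition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (10, 4))
        res = bonferroni_pairwise(x)
        for r, (i, j) in zip(res, itertools.combinations(range(4), 2)):
            _, p_raw = stats.ttest_rel(x[:, i], x[:, j])
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * p_raw))

    def test_shifted_condition_only_its_pairs_significant(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 15)
        x = np.column_stack([base, base + rng.normal(0, 0.1, 15),
                             base + rng.normal(0, 0.1, 15), base + 5.0])
        res = bonferroni_pairwise(x, ["a", "b", "c", "shifted"])
        for r in res:
            if "shifted" in r.pair:
                assert r.p_adjusted < 0.01
            else:
                assert r.p_adjusted > 0.05


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert res["U"] == 0.0

    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert mann_whitney(a, a)["p"] > 0.9

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_count_definition(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, rng.integers(3, 9)).astype(float)
        b = rng.integers(0, 10, rng.integers(3, 9)).astype(float)
        res = mann_whitney(a, b)
        # scipy reports U of the first sample; compare the smaller U
        u_first = res["U"]
        u_min = min(u_first, len(a) * len(b) - u_first)
        assert u_min == pytest.approx(_brute_force_u(a, b))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestRunStudy:
    def _table(self, n_groups=3, n_subj=8, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["control", "compensated", "decompensated"][:n_groups]
        rows = []
        for g in groups:
            for i in range(n_subj):
                for kind in ("frequency_high", "frequency_low", "duration",
                             "gap"):
                    rows.append({
                        "subject_id": f"{g}{i}", "group": g,
                        "deviant_kind": kind,
                        "amplitude_uV": rng.normal(-4, 1.5),
                        "latency_ms": rng.normal(150, 15),
                        "auc_uVms": abs(rng.normal(200, 80)),
                    })
        return pd.DataFrame(rows)

    def test_bundle_bookkeeping(self):
        res = run_study(self._table())
        assert len(res.oneway) == 12  # 3 features x 4 deviants
        assert len(res.tukey) == 12
        assert len(res.rm) == 9  # 3 groups x 3 features
        assert len(res.bonferroni) == 9
        assert all(len(v) == 6 for v in res.bonferroni.values())

    def test_single_group_skips_oneway(self):
        with pytest.warns(UserWarning):
            res = run_study(self._table(n_groups=1))
        assert not res.oneway
        assert len(res.rm) == 3
        assert res.warnings

    def test_reproducible(self):
        t = self._table()
        assert run_study(t).to_json() == run_study(t).to_json()

    def test_incomplete_design_raises(self):
        t = self._table().iloc[:-1]
        with pytest.raises(ValueError):
            run_study(t)

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="columns"):
            run_study(pd.DataFrame({"group": ["a"]}))


class TestCalibration:
    def test_type1_error_rate(self):
        """Null rejection rate of the one-way ANOVA is ~5%."""
        from mmnstudy.experiments import type1_error_rate

        rate = type1_error_rate(n_reps=2000, seed=123)
        assert 0.03 <= rate <= 0.07

    def test_power_under_published_separation(self):
        from mmnstudy.experiments import anova_power

        assert anova_power(n_reps=500, seed=123) > 0.95
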