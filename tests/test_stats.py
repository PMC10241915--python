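"""Statistical battery: closed-form oracles, ANOVA decomposition, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emglfm.stats import (
    balance_tests,
    cohens_d_independent,
    fdr_adjust,
    learning_tests,
    mixed_anova,
    multiple_regression,
    one_sample_t,
    paired_s1_s6_tests,
    paired_t,
    run_regressions,
    simple_regression,
    two_sample_t,
)


class TestTTests:
    def test_two_sample_matches_hand_computation(self):
        # pooled t on a 3-vs-3 hand-checkable dataset
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = two_sample_t(x, y)
        sp2 = (2 * 1.0 + 2 * 4.0) / 4  # pooled variance
        t_hand = (2.0 - 4.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.stat == pytest.approx(t_hand, abs=1e-10)
        assert res.df == (4,)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4), abs=1e-12)

    def test_identical_groups_give_null_result(self):
        res = two_sample_t([3, 3, 3], [3, 3, 3])
        assert res.stat == 0.0 and res.p == 1.0

    def test_welch_flag_changes_df(self):
        x = np.arange(10.0)
        y = np.arange(5.0) * 10
        assert two_sample_t(x, y, pooled=False).df[0] != 13

    def test_one_sample_all_zero_scores(self):
        res = one_sample_t(np.zeros(10))
        assert res.stat == 0.0 and res.p == 1.0

    def test_one_sample_matches_scipy(self, rng):
        x = rng.normal(size=20)
        res = one_sample_t(x, 0.0)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.stat == pytest.approx(ref.statistic)
        assert res.df == (19,)

    def test_paired_identical_gives_null(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.stat == 0.0 and res.p == 1.0

    def test_paired_matches_one_sample_on_differences(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert paired_t(x, y).stat == pytest.approx(one_sample_t(x - y).stat)

    def test_cohens_d_unit_separation(self):
        x = np.array([0.0, 1.0, 2.0] * 10)
        assert cohens_d_independent(x + 1.0, x) == pytest.approx(
            1.0 / x.std(ddof=1), rel=0.05)


class TestMixedAnova:
    def _data(self, rng, n_a=5, n_b=4, m=3, time_effect=0.0, inter=0.0):
        rows = []
        for j in range(n_a + n_b):
            g = "A" if j < n_a else "B"
            base = rng.normal()
            for t in range(m):
                val = base + time_effect * t + (inter * t if g == "A" else 0)
                rows.append({"subject": f"s{j}", "group": g, "session": t + 1,
                             "dv": val + rng.normal()})
        return pd.DataFrame(rows)

    def test_matches_independent_oracle(self, rng):
        """F values agree with pingouin's projection-based computation."""
        pg = pytest.importorskip("pingouin")
        df = self._data(rng, time_effect=0.4, inter=0.3)
        ours = mixed_anova(df, "dv").set_index("effect")
        ref = pg.mixed_anova(df, dv="dv", within="session", between="group",
                             subject="subject").set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert ours.loc["session", "F"] == pytest.approx(ref.loc["session", "F"], abs=1e-8)
        assert ours.loc["session*group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)

    def test_sums_of_squares_are_conserved(self, rng):
        df = self._data(rng, time_effect=0.5)
        tbl = mixed_anova(df, "dv").set_index("effect")
        y = df["dv"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert tbl.ss.sum() == pytest.approx(ss_total, abs=1e-8)

    def test_constant_within_subject_kills_time_effect(self):
        rows = [{"subject": f"s{j}", "group": "A" if j < 3 else "B",
                 "session": t, "dv": float(j)}
                for j in range(6) for t in (1, 2, 3)]
        tbl = mixed_anova(pd.DataFrame(rows), "dv").set_index("effect")
        assert tbl.loc["session", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_design_dfs(self, rng):
        df = self._data(rng, n_a=36, n_b=36, m=6)
        tbl = mixed_anova(df, "dv").set_index("effect")
        assert (tbl.loc["session", "df1"], tbl.loc["session", "df2"]) == (5, 350)
        assert (tbl.loc["group", "df1"], tbl.loc["group", "df2"]) == (1, 70)
        assert (tbl.loc["session*group", "df1"], tbl.loc["session*group", "df2"]) == (5, 350)

    def test_incomplete_subject_rejected(self, rng):
        df = self._data(rng).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(df, "dv")

    def test_gg_epsilon_in_valid_range(self, rng):
        df = self._data(rng, m=4)
        tbl = mixed_anova(df, "dv", correction="gg")
        assert 1 / 3 <= tbl.attrs["epsilon"] <= 1.0


class TestFdr:
    @staticmethod
    def _bh_oracle(p, q=0.05):
        """Brute-force step-up over all ranks."""
        p = np.asarray(p)
        order = np.argsort(p)
        m = p.size
        passing = [k for k in range(1, m + 1) if p[order[k - 1]] <= q * k / m]
        k_star = max(passing) if passing else 0
        rej = np.zeros(m, bool)
        rej[order[:k_star]] = True
        return rej

    def test_flags_match_step_up_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            p = rng.uniform(size=9)
            rej, _, _ = fdr_adjust(p)
            assert np.array_equal(rej, self._bh_oracle(p))

    def test_all_zero_pvalues_all_significant(self):
        rej, _, thr = fdr_adjust(np.zeros(5))
        assert rej.all() and thr == 0.0

    def test_single_test_reduces_to_raw_threshold(self):
        rej, p_adj, thr = fdr_adjust([0.04])
        assert rej[0] and thr == pytest.approx(0.04)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_adjust([])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestRegressions:
    def test_exact_linear_relation(self):
        x = np.arange(20.0)
        res = simple_regression(x, 2 * x + 1)
        assert res.stat == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_beta_equals_pearson_r(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = simple_regression(x, y)
        assert res.stat == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_multiple_regression_recovers_coefficients(self, rng):
        n, k = 36, 9
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
        beta = rng.normal(size=k)
        y = X.to_numpy() @ beta
        res = multiple_regression(X, y)
        assert res["df"] == (9, 26)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-10)
        # recovered standardized betas correspond to beta_i * sd(x_i)/sd(y)
        sy = np.std(y, ddof=1)
        for i, c in enumerate(X.columns):
            expected = beta[i] * X[c].std(ddof=1) / sy
            assert res["beta"][c] == pytest.approx(expected, abs=1e-8)

    def test_collinear_predictors_named(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        X["c"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            multiple_regression(X, rng.normal(size=30))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            simple_regression([1, 2, 3], [1, 2, 3])


class TestBatteries:
    def test_balance_df_is_70_for_full_cohorts(self, rng):
        df = pd.DataFrame({
            "group": ["AOT"] * 36 + ["CTRL"] * 36,
            "age": rng.normal(26, 4, 72),
        })
        res = balance_tests(df, ["age"])
        assert res[0].df == (70,)

    def test_learning_tests_dfs_and_zero_case(self):
        rows = []
        for g in ("AOT", "CTRL"):
            for j in range(36):
                for s in (1, 6):
                    rows.append({"subject": f"{g}{j}", "group": g, "session": s,
                                 "ga_corrected": 0.0, "fl_corrected": 0.0,
                                 "md_corrected": 0.0})
        res = learning_tests(pd.DataFrame(rows))
        by_label = {r.label: r for r in res}
        assert by_label["learning:ga:AOT"].df == (35,)
        assert by_label["learning:ga:between"].df == (70,)
        assert by_label["learning:ga:AOT"].stat == 0.0

    def test_paired_battery_equal_sessions_give_null(self):
        rows = []
        for g in ("AOT", "CTRL"):
            for j in range(10):
                for s in (1, 6):
                    rows.append({"subject": f"{g}{j}", "group": g, "session": s,
                                 "muscle": "OP", "scope": "full_trial",
                                 "r_squared": 0.4 + 0.01 * j})
        res = paired_s1_s6_tests(pd.DataFrame(rows))
        assert all(r.stat == 0.0 and r.p == 1.0 for r in res)

    def test_h3_phase_battery_has_nine_cells_per_group(self, small_study):
        from emglfm import baseline_correct, delta_table, similarity_delta
        from emglfm.pipeline import similarity_table

        scores = similarity_table(small_study)
        deltas = delta_table(small_study.behavior)
        sdel = similarity_delta(scores)
        out = run_regressions("H3", deltas, scores, sdel,
                              scopes=("reaching", "holding", "transport"))
        assert (out.groupby("group").size() == 9).all()
        assert set(out.columns) >= {"beta", "r_squared", "p", "p_fdr", "significant_fdr"}

    def test_between_group_power_at_programmed_advantage(self):
        """A strong programmed AOT decay advantage is detected reliably."""
        from emglfm import GeneratorConfig, baseline_correct, simulate_study

        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=seed, ga_decay_aot=0.35, ga_decay_ctrl=0.05)
            corrected = baseline_correct(simulate_study(cfg).behavior)
            res = {r.label: r for r in learning_tests(corrected)}
            hits += res["learning:ga:between"].p < 0.05
        assert hits / n_rep >= 0.8

    def test_null_permutation_pvalues_are_uniform(self, rng):
        """Permuted predictor -> p-values uniform (KS test)."""
        n = 40
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        pvals = []
        for _ in range(500):
            pvals.append(simple_regression(rng.permutation(x), y).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
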