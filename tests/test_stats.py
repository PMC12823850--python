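import numpy as np
import pandas as pd
import pytest

from bbnet import stats as bst


class TestPairedT:
    def test_hand_computed_statistic(self):
        # differences [1, 2, 3]: t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        y = np.array([10.0, 20.0, 30.0])
        x = y + np.array([1.0, 2.0, 3.0])
        res = bst.paired_t(x, y)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_agrees_with_scipy(self, rng):
        from scipy.stats import ttest_rel
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        res = bst.paired_t(x, y)
        ref = ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_raw == pytest.approx(ref.pvalue)

    def test_null_simulation_type_one_error(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            if bst.paired_t(x, y).p_raw < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_constant_differences_raise(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            bst.paired_t(y + 2.0, y)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            bst.paired_t([1.0, 2.0], [0.0, 1.0])


class TestCohensD:
    def test_unit_mean_unit_sd_is_large(self, rng):
        d = rng.standard_normal(4000)
        d = (d - d.mean()) / d.std(ddof=1) + 1.0  # mean 1, sd 1 exactly
        y = rng.standard_normal(4000)
        dz, label = bst.cohens_d_paired(y + d, y)
        assert dz == pytest.approx(1.0, abs=1e-9)
        assert label == "large"

    def test_half_mean_is_medium(self, rng):
        d = rng.standard_normal(4000)
        d = (d - d.mean()) / d.std(ddof=1) + 0.5
        y = rng.standard_normal(4000)
        dz, label = bst.cohens_d_paired(y + d, y)
        assert dz == pytest.approx(0.5, abs=1e-9)
        assert label == "medium"

    def test_zero_mean_is_small(self, rng):
        d = rng.standard_normal(1000)
        d = d - d.mean()
        y = rng.standard_normal(1000)
        dz, label = bst.cohens_d_paired(y + d, y)
        assert dz == pytest.approx(0.0, abs=1e-9)
        assert label == "small"

    @pytest.mark.parametrize("d, label", [
        (0.81, "large"), (-0.81, "large"), (0.8, "medium"),
        (0.4, "medium"), (0.39, "small"), (-0.2, "small"),
    ])
    def test_label_cutoffs(self, d, label):
        assert bst.effect_size_label(d) == label


class TestFDR:
    def test_stepup_accepts_all_when_every_rank_passes(self):
        # thresholds i*q/m = .0125, .025, .0375, .05 — all pass
        reject, _ = bst.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_large_pvalues_all_retained(self):
        reject, _ = bst.bh_fdr([0.5, 0.6, 0.9], q=0.05)
        assert not reject.any()

    def test_single_test_reduces_to_raw_threshold(self):
        reject, p_adj = bst.bh_fdr([0.04], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.04)

    def test_adjusted_p_monotone_in_rank(self, rng):
        p = rng.uniform(size=40)
        _, p_adj = bst.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bst.bh_fdr([])

    def test_global_null_family_wise_rate_at_most_q(self):
        rng = np.random.default_rng(11)
        reps, m, q = 2000, 50, 0.05
        any_rejection = sum(
            bst.bh_fdr(rng.uniform(size=m), q=q)[0].any()
            for _ in range(reps))
        rate = any_rejection / reps
        se = np.sqrt(q * (1 - q) / reps)
        assert rate <= q + 3 * se


class TestPearson:
    def test_perfect_linear_relation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = bst.pearson_r(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        r, _ = bst.pearson_r(a, -a)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        r, _ = bst.pearson_r(a, b)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_affine_invariance_up_to_slope_sign(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        r0, _ = bst.pearson_r(a, b)
        r1, _ = bst.pearson_r(3.0 * a - 7.0, b)
        r2, _ = bst.pearson_r(-2.0 * a + 1.0, b)
        assert r1 == pytest.approx(r0)
        assert r2 == pytest.approx(-r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bst.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationMap:
    def _power_table(self, rng, n=30):
        cols = [f"CH{i}" for i in range(14)]
        return pd.DataFrame(rng.standard_normal((n, 14)), columns=cols,
                            index=[f"S{i}" for i in range(n)])

    def test_planted_effect_is_flagged_positive(self, rng):
        power = self._power_table(rng)
        behavior = 3.0 * power["CH2"] + 0.1 * rng.standard_normal(len(power))
        out = bst.correlation_map(power, behavior)
        row = out.set_index("predictor").loc["CH2"]
        assert row["flag"] == "positive"

    def test_permuted_behavior_flag_rate_near_alpha(self, rng):
        power = self._power_table(rng, n=25)
        flags = 0
        total = 0
        for _ in range(60):
            behavior = pd.Series(rng.standard_normal(len(power)),
                                 index=power.index)
            out = bst.correlation_map(power, behavior, alpha=0.05)
            flags += (out["flag"] != "ns").sum()
            total += len(out)
        assert flags / total == pytest.approx(0.05, abs=0.03)

    def test_constant_behavior_is_an_error(self, rng):
        power = self._power_table(rng)
        with pytest.raises(ValueError):
            bst.correlation_map(power, pd.Series(1.0, index=power.index))

    def test_subject_mismatch_is_an_error(self, rng):
        power = self._power_table(rng)
        behavior = pd.Series(rng.standard_normal(3),
                             index=["S0", "S1", "ZZZ"])
        with pytest.raises(ValueError):
            bst.correlation_map(power, behavior)


def _balanced_design(rng, group_effects, state_effects, interaction=0.0,
                     n_cell=10, noise=1.0):
    rows = []
    for gi, g in enumerate("ABC"):
        for si, s in enumerate(["Pre-BB", "Post-BB"]):
            mu = group_effects[gi] + state_effects[si]
            if g == "A" and s == "Post-BB":
                mu += interaction
            for _ in range(n_cell):
                rows.append({"y": mu + noise * rng.standard_normal(),
                             "group": g, "state": s})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_observations_give_zero_f(self):
        df = pd.DataFrame({"y": 5.0,
                           "group": list("AABB") * 2,
                           "state": ["Pre-BB"] * 4 + ["Post-BB"] * 4})
        table = bst.two_way_anova(df["y"], df["group"], df["state"]).table
        assert np.allclose(table.loc[["group", "state", "interaction"], "F"],
                           0.0)

    def test_pure_group_effect_dominates(self, rng):
        df = _balanced_design(rng, [0.0, 5.0, 10.0], [0.0, 0.0], noise=0.01)
        aov = bst.two_way_anova(df["y"], df["group"], df["state"])
        assert aov.table.loc["group", "eta_sq"] > 0.99
        assert aov.table.loc["state", "p"] > 0.01

    def test_matches_hand_sums_of_squares(self, rng):
        # balanced 3x2 design: type II == classic sequential decomposition
        df = _balanced_design(rng, [0.0, 1.0, 2.0], [0.0, 0.7],
                              interaction=0.5, n_cell=8)
        aov = bst.two_way_anova(df["y"], df["group"], df["state"])
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        g_means = df.groupby("group")["y"].mean()
        s_means = df.groupby("state")["y"].mean()
        cell = df.groupby(["group", "state"])["y"].mean()
        n_g = len(df) / 3
        n_s = len(df) / 2
        n_c = len(df) / 6
        ss_g = (n_g * (g_means - grand) ** 2).sum()
        ss_s = (n_s * (s_means - grand) ** 2).sum()
        ss_cells = (n_c * (cell - grand) ** 2).sum()
        ss_int = ss_cells - ss_g - ss_s
        ss_res = ss_total - ss_cells
        f_g = (ss_g / 2) / (ss_res / (len(df) - 6))
        assert aov.table.loc["group", "sum_sq"] == pytest.approx(ss_g)
        assert aov.table.loc["interaction", "sum_sq"] == pytest.approx(ss_int)
        assert aov.table.loc["group", "F"] == pytest.approx(f_g)

    def test_eta_squared_fractions_sum_to_one_when_balanced(self, rng):
        df = _balanced_design(rng, [0, 1, 2], [0, 1], interaction=1.0)
        aov = bst.two_way_anova(df["y"], df["group"], df["state"])
        assert aov.table["eta_sq"].sum() == pytest.approx(1.0)

    def test_empty_cell_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "group": ["A", "A", "B", "B"],
                           "state": ["Pre-BB"] * 4})
        with pytest.raises(ValueError):
            bst.two_way_anova(df["y"], df["group"], df["state"])


class TestSampleSize:
    def test_huge_effect_needs_the_minimum(self):
        assert bst.required_n_paired(50.0) == 2

    def test_agrees_with_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestPower
        n = bst.required_n_paired(0.5, alpha=0.05, power=0.8)
        ref = TTestPower().solve_power(effect_size=0.5, alpha=0.05, power=0.8)
        assert n == int(np.ceil(ref))

    def test_monte_carlo_power_confirms_required_n(self):
        d, alpha, power = 0.5, 0.05, 0.8
        n = bst.required_n_paired(d, alpha, power)
        rng = np.random.default_rng(3)
        reps = 10_000

        def mc_power(m):
            diffs = rng.standard_normal((reps, m)) + d
            t = diffs.mean(1) / (diffs.std(1, ddof=1) / np.sqrt(m))
            from scipy.stats import t as tdist
            crit = tdist.ppf(1 - alpha / 2, m - 1)
            return np.mean(np.abs(t) > crit)

        assert mc_power(n) >= power - 0.02
        assert mc_power(n - 1) < power + 0.02

    def test_monotone_in_effect_size(self):
        ns = [bst.required_n_paired(d) for d in (0.3, 0.5, 0.8, 1.2)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bst.required_n_paired(0.0)
        with pytest.raises(ValueError):
            bst.required_n_paired(0.5, alpha=1.5)
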