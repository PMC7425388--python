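"""Group statistics: mixed ANOVA, MANOVA gating, Kruskal-Dunn, power."""

import numpy as np
import pandas as pd
import pytest

from nptpipe.stats import (
    anova_power,
    art_anova,
    holm_sidak,
    kruskal_dunn,
    manova_then_univariate,
    monte_carlo_anova_power,
    power_sample_size,
    rm_anova,
)


def mixed_frame(groups, within_levels, values):
    """Long-format frame: values[group][subject][level]."""
    rows = []
    sid = 0
    for g, subs in zip(groups, values):
        for subj in subs:
            for lev, val in zip(within_levels, subj):
                rows.append({"subject_id": f"s{sid}", "group": g,
                             "variable": lev, "value": float(val)})
            sid += 1
    return pd.DataFrame(rows)


class TestHolmSidak:
    def test_adjusted_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(0.001, 0.9, 12)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty(self):
        assert holm_sidak([]).size == 0


class TestRmAnova:
    def test_textbook_balanced_design_matches_ss_oracle(self):
        """Hand-computed sums of squares for a 2x2 mixed design.

        Between factor A (2 groups x 3 subjects), within factor B (2
        levels). The oracle computes SS_A, SS_B, SS_AB and their error
        terms explicitly from cell totals.
        """
        values = [
            [[3.0, 5.0], [4.0, 6.0], [5.0, 10.0]],
            [[6.0, 7.0], [7.0, 9.0], [8.0, 11.0]],
        ]
        df = mixed_frame(["g1", "g2"], ["b1", "b2"], values)
        res = rm_anova(df, alpha=1.1)  # keep posthoc off regardless of p

        Y = np.array(values)  # (group, subject, level)
        gm = Y.mean()
        n, k = 3, 2  # subjects per group, within levels
        ss_a = 2 * n * 0 + k * n * ((Y.mean(axis=(1, 2)) - gm) ** 2).sum()
        ss_b = 2 * n * ((Y.mean(axis=(0, 1)) - gm) ** 2).sum()
        cell = Y.mean(axis=1)
        ss_ab = n * ((cell - Y.mean(axis=(1, 2))[:, None]
                      - Y.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        subj_mean = Y.mean(axis=2)
        ss_subj = k * ((subj_mean - Y.mean(axis=(1, 2))[:, None]) ** 2).sum()
        ss_total = ((Y - gm) ** 2).sum()
        ss_err_within = ss_total - ss_a - ss_b - ss_ab - ss_subj

        df_a, df_subj = 1, 2 * (n - 1)
        df_b, df_ab = 1, 1
        df_err = df_subj * (k - 1)
        f_a = (ss_a / df_a) / (ss_subj / df_subj)
        f_b = (ss_b / df_b) / (ss_err_within / df_err)
        f_ab = (ss_ab / df_ab) / (ss_err_within / df_err)

        assert res.effect("group")["F"] == pytest.approx(f_a, rel=1e-9)
        assert res.effect("variable")["F"] == pytest.approx(f_b, rel=1e-9)
        assert res.effect("interaction")["F"] == pytest.approx(f_ab, rel=1e-9)

    def test_identical_groups_give_zero_group_effect(self):
        subj = [[3.0, 5.0], [4.0, 6.0], [5.0, 7.0], [6.0, 8.0]]
        df = mixed_frame(["g1", "g2"], ["b1", "b2"], [subj, subj])
        res = rm_anova(df)
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-9)

    def test_significant_interaction_attaches_lsm_and_posthoc(self, rng):
        g1 = [[x + rng.normal(0, .1), x + rng.normal(0, .1)] for x in rng.normal(0, .2, 8)]
        g2 = [[x + rng.normal(0, .1), x + 3 + rng.normal(0, .1)]
              for x in rng.normal(0, .2, 8)]
        res = rm_anova(mixed_frame(["g1", "g2"], ["b1", "b2"], [g1, g2]))
        assert res.effect("interaction")["p"] < 0.05
        assert res.lsm is not None and len(res.lsm) == 4
        assert res.posthoc is not None
        assert (res.posthoc["p_adj"] >= res.posthoc["p_unc"] - 1e-12).all()
        # LSM equals the plain cell mean in this balanced design
        cell = res.lsm.set_index(["group", "variable"])["lsm"]
        df = mixed_frame(["g1", "g2"], ["b1", "b2"], [g1, g2])
        expected = df.groupby(["group", "variable"])["value"].mean()
        assert np.allclose(cell.sort_index(), expected.sort_index())

    def test_single_group_rejected(self):
        df = mixed_frame(["g1"], ["b1", "b2"], [[[1.0, 2.0], [2.0, 3.0]]])
        with pytest.raises(ValueError):
            rm_anova(df)


class TestManova:
    def make_frame(self, rng, n=60, effect=0.0, shared=1.0):
        df = pd.DataFrame({
            "group": np.repeat(["A", "B", "C"], n // 3),
            "size_class": np.tile(["short", "long"], n // 2),
        })
        base = rng.normal(size=n) * shared
        shift = np.repeat([0.0, effect, 2 * effect], n // 3)
        df["frontal"] = base + rng.normal(size=n) + shift
        df["parietal"] = base + rng.normal(size=n) + shift
        return df

    def test_identical_dvs_flag_assumption_violation(self, rng):
        df = self.make_frame(rng)
        df["parietal"] = df["frontal"]
        with pytest.warns(UserWarning, match="assumption"):
            with pytest.raises(ValueError, match="collinear"):
                manova_then_univariate(df, remove_outliers=False)

    def test_no_effect_large_n_lambda_near_one(self, rng):
        df = self.make_frame(rng, n=600, effect=0.0)
        res = manova_then_univariate(df, remove_outliers=False)
        assert res.wilks_lambda > 0.97

    def test_strong_effect_gates_univariate_followups(self, rng):
        df = self.make_frame(rng, n=90, effect=1.5)
        res = manova_then_univariate(df, remove_outliers=False)
        assert res.p < 0.05
        assert set(res.univariate) == {"frontal", "parietal"}
        for tab in res.univariate.values():
            assert {"Source", "F", "p"} <= set(tab.columns)

    def test_wilks_f_relation_on_one_df_contrast(self, rng):
        """For 2 groups and p = 2 DVs: F = (1 - L)/L * (N - g - 1)/p exactly."""
        n = 40
        df = pd.DataFrame({
            "group": np.repeat(["A", "B"], n // 2),
            "size_class": ["short"] * n,
            "frontal": rng.normal(size=n),
            "parietal": rng.normal(size=n),
        })
        res = manova_then_univariate(df, remove_outliers=False)
        lam = res.wilks_lambda
        expected_f = (1 - lam) / lam * (n - 2 - 1) / 2
        assert res.F == pytest.approx(expected_f, rel=1e-6)

    def test_single_dv_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_then_univariate(self.make_frame(rng), dvs=("frontal",))

    def test_outlier_removal_reports_count(self, rng):
        df = self.make_frame(rng, n=90)
        df.loc[0, "frontal"] = 40.0
        res = manova_then_univariate(df)
        assert res.n_outliers_removed >= 1


class TestArtAnova:
    def test_detects_shift_on_skewed_data(self, rng):
        n = 60
        df = pd.DataFrame({
            "group": np.repeat(["A", "B", "C"], n // 3),
            "size_class": np.tile(["short", "long"], n // 2),
        })
        df["y"] = rng.exponential(1.0, n) + np.repeat([0.0, 0.0, 2.0], n // 3)
        tab = art_anova(df, "y", "size_class", "group")
        group_row = tab[tab["Source"] == "C(group)"].iloc[0]
        assert group_row["p"] < 0.01


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        # the three groups hold the same sample -> all mean ranks equal
        vals = [1.0, 2.0, 3.0] * 3
        grps = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = kruskal_dunn(vals, grps)
        assert out["H"] == pytest.approx(0.0, abs=1e-12)
        assert out["posthoc"] is None

    def test_worked_example_rank_formula(self):
        """{1,2,3},{4,5,6},{7,8,9}: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1) = 7.2."""
        vals = np.arange(1.0, 10.0)
        grps = np.repeat(["a", "b", "c"], 3)
        out = kruskal_dunn(vals, grps)
        assert out["H"] == pytest.approx(7.2, rel=1e-12)
        assert out["posthoc"] is not None
        # Dunn z for extreme groups: (2 - 8) / sqrt((9*10/12)*(2/3))
        z_ac = out["posthoc"].query("A == 'a' and B == 'c'")["z"].iloc[0]
        assert abs(z_ac) == pytest.approx(6 / np.sqrt(7.5 * 2 / 3), rel=1e-12)

    def test_power_increases_with_shift(self, rng):
        rates = []
        for shift in (0.0, 1.0, 2.0):
            rej = 0
            for _ in range(200):
                vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                                       rng.normal(shift, 1, 10)])
                grps = np.repeat(["a", "b", "c"], 10)
                rej += kruskal_dunn(vals, grps)["p"] < 0.05
            rates.append(rej / 200)
        assert rates[0] < rates[1] < rates[2]

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1, 2, 3, 4], ["a", "a", "b", "b"])

    def test_all_nan_group_rejected(self):
        vals = [1.0, 2.0, 3.0, 4.0, np.nan, np.nan]
        grps = ["a", "a", "b", "b", "c", "c"]
        with pytest.raises(ValueError, match="observation"):
            kruskal_dunn(vals, grps)


class TestPower:
    def test_design_parameters_give_nine_per_group(self):
        assert power_sample_size(0.3, 0.15, 0.05, 0.95, 3) == 9

    def test_monotone_in_target_power(self):
        n80 = power_sample_size(power=0.80)
        n95 = power_sample_size(power=0.95)
        n99 = power_sample_size(power=0.99)
        assert n80 <= n95 <= n99

    def test_analytic_power_matches_monte_carlo(self):
        means = [0.0, 0.15, 0.3]
        exact = anova_power(means, 0.15, 9)
        mc = monte_carlo_anova_power(means, 0.15, 9, n_sims=2000, seed=0)
        assert mc == pytest.approx(exact, abs=0.03)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(detectable_mean=-1)
        with pytest.raises(ValueError):
            power_sample_size(power=1.5)
        with pytest.raises(ValueError):
            power_sample_size(n_groups=1)

    def test_conventions_differ(self):
        n_mid = power_sample_size(convention="extremes-midpoint")
        n_sd = power_sample_size(convention="sd-of-means")
        assert n_sd < n_mid
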