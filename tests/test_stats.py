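import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from keyscore import (
    bonferroni,
    remove_outliers_3sd,
    rm_anova_oneway,
    rm_anova_twoway,
    ttest_two_sample,
)


def long_table(wide: np.ndarray, factor="cond") -> pd.DataFrame:
    n, k = wide.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            factor: list(range(k)) * n,
            "value": wide.ravel(),
        }
    )


class TestOneWayRMAnova:
    def test_constant_data_F_zero(self):
        df = long_table(np.full((6, 3), 2.5))
        res = rm_anova_oneway(df, "value", "cond", "subject")
        assert res["cond"].F == 0.0

    def test_two_conditions_equal_paired_t_squared(self, rng):
        wide = rng.normal(size=(12, 2))
        res = rm_anova_oneway(long_table(wide), "value", "cond", "subject")
        t = sps.ttest_rel(wide[:, 0], wide[:, 1])
        assert res["cond"].F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res["cond"].p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        wide = rng.normal(size=(10, 4))
        df = long_table(wide)
        res = rm_anova_oneway(df, "value", "cond", "subject")["cond"]
        ref = pg.rm_anova(data=df, dv="value", within="cond", subject="subject")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)
        assert (res.df1, res.df2) == (3, 27)

    def test_partial_eta_squared_identity(self, rng):
        wide = rng.normal(size=(8, 3))
        res = rm_anova_oneway(long_table(wide), "value", "cond", "subject")["cond"]
        assert res.partial_eta_sq == pytest.approx(
            res.F * res.df1 / (res.F * res.df1 + res.df2), rel=1e-12
        )

    def test_missing_cell_rejected(self, rng):
        df = long_table(rng.normal(size=(5, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            rm_anova_oneway(df, "value", "cond", "subject")

    def test_gg_correction_shrinks_dfs(self, rng):
        wide = rng.normal(size=(10, 4))
        wide[:, 0] *= 4  # break sphericity
        plain = rm_anova_oneway(long_table(wide), "value", "cond", "subject")["cond"]
        gg = rm_anova_oneway(long_table(wide), "value", "cond", "subject", correction="gg")["cond"]
        assert gg.df1 < plain.df1 and gg.F == plain.F


class TestTwoWayRMAnova:
    @staticmethod
    def long2(X):
        n, a, b = X.shape
        rows = [
            {"subject": s, "A": f"a{i}", "B": f"b{j}", "value": X[s, i, j]}
            for s in range(n)
            for i in range(a)
            for j in range(b)
        ]
        return pd.DataFrame(rows)

    def test_constant_data_all_F_zero(self):
        res = rm_anova_twoway(self.long2(np.full((5, 2, 2), 1.0)), "value", ("A", "B"), "subject")
        assert all(e.F == 0.0 for e in res.effects.values())

    def test_hand_computed_2x2(self):
        # 4 subjects x A(2) x B(2); expected values worked out once from the
        # classical decomposition of this fixed dataset: factor-level means
        # a0=4.625, a1=6.625 around the grand mean 5.625 give
        # SS_A = 4*2*(1^2+1^2) = 16 with SS_AxS = 4.5, hence F_A = 32/3;
        # SS_B = 36 with SS_BxS = 0.5 (F_B = 216); SS_AB = 2.25 with
        # SS_ABxS = 0.25 (F_AB = 27)
        X = np.array(
            [
                [[3.0, 5.0], [4.0, 8.0]],
                [[2.0, 4.0], [3.0, 7.0]],
                [[5.0, 8.0], [5.0, 9.0]],
                [[4.0, 6.0], [7.0, 10.0]],
            ]
        )
        res = rm_anova_twoway(self.long2(X), "value", ("A", "B"), "subject")
        a = res["A"]
        assert (a.df1, a.df2) == (1, 3)
        assert a.F == pytest.approx(32 / 3, rel=1e-9)
        assert a.partial_eta_sq == pytest.approx(16 / 20.5, rel=1e-9)
        assert res["B"].F == pytest.approx(216.0, rel=1e-9)
        assert res["A * B"].F == pytest.approx(27.0, rel=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(9, 3, 2))
        df = self.long2(X)
        res = rm_anova_twoway(df, "value", ("A", "B"), "subject")
        ref = pg.rm_anova(
            data=df.rename(columns={"value": "dv_"}), dv="dv_",
            within=["A", "B"], subject="subject", effsize="np2",
        ).set_index("Source")
        for effect in ["A", "B", "A * B"]:
            assert res[effect].F == pytest.approx(float(ref.loc[effect, "F"]), rel=1e-6)
            assert res[effect].p == pytest.approx(float(ref.loc[effect, "p_unc"]), rel=1e-6)
            assert res[effect].partial_eta_sq == pytest.approx(
                float(ref.loc[effect, "np2"]), rel=1e-6
            )

    def test_missing_cell_rejected(self, rng):
        df = self.long2(rng.normal(size=(4, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            rm_anova_twoway(df, "value", ("A", "B"), "subject")

    def test_to_frame_shape(self, rng):
        res = rm_anova_twoway(self.long2(rng.normal(size=(5, 2, 3))), "value", ("A", "B"), "subject")
        frame = res.to_frame()
        assert list(frame["effect"]) == ["A", "B", "A * B"]
        assert set(frame.columns) >= {"df1", "df2", "F", "p", "partial_eta_sq"}


class TestWelchTTest:
    def test_identical_samples(self):
        res = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_closed_form_welch(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.3, 2, 45)
        res = ttest_two_sample(x, y)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert res.df != int(res.df)  # Welch: fractional df
        assert res.ci_low < x.mean() - y.mean() < res.ci_high

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(1, 1, size=25)
        a, b = ttest_two_sample(x, y), ttest_two_sample(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)
        assert a.cohen_d == pytest.approx(b.cohen_d)

    def test_constant_equal_samples_convention(self):
        res = ttest_two_sample([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0 and res.cohen_d == 0.0


class TestOutlierRemoval:
    def test_all_equal_nothing_removed(self):
        kept, n = remove_outliers_3sd([2.0] * 10)
        assert n == 0 and kept.size == 10

    def test_extreme_value_removed(self, rng):
        x = rng.normal(size=200)
        mu, sd = x.mean(), x.std(ddof=1)
        x = np.append(x, mu + 5 * sd)
        kept, n = remove_outliers_3sd(x)
        assert n >= 1
        assert mu + 5 * sd not in kept

    def test_single_pass_idempotent(self, rng):
        x = np.append(rng.normal(size=100), 8.0)
        kept, _ = remove_outliers_3sd(x)
        kept2, n2 = remove_outliers_3sd(kept)
        # statistics re-estimated on the kept data may flag new points; the
        # operation itself never re-trims within one call
        kept_again, n_again = remove_outliers_3sd(x)
        assert np.array_equal(kept, kept_again)

    def test_per_group_statistics(self):
        values = [0.0, 0.1, -0.1, 0.05, 100.0, 100.1, 99.9, 100.05]
        groups = ["a"] * 4 + ["b"] * 4
        kept, n = remove_outliers_3sd(values, groups)
        assert n == 0  # each value is typical within its own group


def test_bonferroni_caps_at_one():
    adj = bonferroni([0.01, 0.2, 0.5], m=3)
    assert adj.tolist() == pytest.approx([0.03, 0.6, 1.0])
    assert bonferroni([0.04]).tolist() == [0.04]
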