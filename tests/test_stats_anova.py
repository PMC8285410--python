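import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from epimem.stats import mixed_anova, one_sample_t, tukey_hsd
from epimem.types import DegenerateDataError


def _long(rng, k=3, n=6, a=3, b=1, effects=(0.5, 0.3, 0.2)):
    """Balanced split-plot table with known group/within structure."""
    rows = []
    for g in range(k):
        for s in range(n):
            sid = f"g{g}s{s}"
            subj_eff = rng.normal(0, 0.5)
            for ia in range(a):
                for ib in range(b):
                    mu = effects[0] * g + effects[1] * ia + effects[2] * ib
                    rows.append(
                        {
                            "subject": sid,
                            "group": f"G{g}",
                            "A": f"a{ia}",
                            "B": f"b{ib}",
                            "y": mu + subj_eff + rng.normal(0, 1),
                        }
                    )
    return pd.DataFrame(rows)


class TestAnalyticIdentities:
    def test_two_group_between_equals_pooled_t_squared(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(27)],
                "g": ["x"] * 12 + ["y"] * 15,
                "v": np.r_[x, y],
            }
        )
        tab = mixed_anova(df, dv="v", subject="subject", between="g")
        t, p = sps.ttest_ind(x, y)
        assert tab.table.F[0] == pytest.approx(t**2, rel=1e-12)
        assert tab.table.p[0] == pytest.approx(p, rel=1e-12)

    def test_two_level_within_equals_paired_t_squared(self, rng):
        pre, post = rng.normal(0, 1, 14), rng.normal(0.5, 1, 14)
        df = pd.DataFrame(
            {
                "subject": np.repeat([f"s{i}" for i in range(14)], 2),
                "cond": ["pre", "post"] * 14,
                "v": np.c_[pre, post].ravel(),
            }
        )
        tab = mixed_anova(df, dv="v", subject="subject", within="cond")
        t, p = sps.ttest_rel(pre, post)
        assert tab.table.F[0] == pytest.approx(t**2, rel=1e-12)
        assert tab.table.p[0] == pytest.approx(p, rel=1e-12)


class TestOracleEquivalence:
    def test_three_by_three_matches_pingouin(self, rng):
        df = _long(rng, k=3, n=6, a=3)
        mine = mixed_anova(df, dv="y", subject="subject", between="group", within="A")
        ref = pg.mixed_anova(df, dv="y", subject="subject", between="group", within="A")
        ref_f = dict(zip(ref["Source"], ref["F"]))
        assert mine.F("group") == pytest.approx(ref_f["group"], rel=1e-10)
        assert mine.F("A") == pytest.approx(ref_f["A"], rel=1e-10)
        assert mine.F("A*group") == pytest.approx(ref_f["Interaction"], rel=1e-10)

    def test_three_way_split_plot_matches_mean_decomposition(self, rng):
        """2 (within) x 2 (within) x 3 (between) against an independent
        cell-mean decomposition of the sums of squares."""
        k, n, a, b = 3, 5, 2, 2
        df = _long(rng, k=k, n=n, a=a, b=b, effects=(0.4, 0.6, 0.5))
        mine = mixed_anova(df, dv="y", subject="subject", between="group", within=["A", "B"])

        piv = df.pivot_table(index=["group", "subject"], columns=["A", "B"], values="y")
        Y = piv.to_numpy().reshape(k, n, a, b)
        GM = Y.mean()
        m_g = Y.mean(axis=(1, 2, 3))
        m_s = Y.mean(axis=(2, 3))
        m_a = Y.mean(axis=(0, 1, 3))
        m_b = Y.mean(axis=(0, 1, 2))
        m_ag = Y.mean(axis=(1, 3))
        m_bg = Y.mean(axis=(1, 2))
        m_ab = Y.mean(axis=(0, 1))
        m_abg = Y.mean(axis=1)
        m_as = Y.mean(axis=3)
        m_bs = Y.mean(axis=2)

        ss = {}
        ss["group"] = n * a * b * np.sum((m_g - GM) ** 2)
        ss["subj"] = a * b * np.sum((m_s - m_g[:, None]) ** 2)
        ss["A"] = k * n * b * np.sum((m_a - GM) ** 2)
        ss["A*group"] = n * b * np.sum((m_ag - m_a[None, :] - m_g[:, None] + GM) ** 2)
        ss["errA"] = b * np.sum((m_as - m_ag[:, None, :] - m_s[..., None] + m_g[:, None, None]) ** 2)
        ss["B"] = k * n * a * np.sum((m_b - GM) ** 2)
        ss["B*group"] = n * a * np.sum((m_bg - m_b[None, :] - m_g[:, None] + GM) ** 2)
        ss["errB"] = a * np.sum((m_bs - m_bg[:, None, :] - m_s[..., None] + m_g[:, None, None]) ** 2)
        ss["A*B"] = k * n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + GM) ** 2)
        ss["A*B*group"] = n * np.sum(
            (
                m_abg
                - m_ab[None]
                - m_ag[:, :, None]
                - m_bg[:, None, :]
                + m_a[None, :, None]
                + m_b[None, None, :]
                + m_g[:, None, None]
                - GM
            )
            ** 2
        )
        ss["errAB"] = np.sum(
            (
                Y
                - m_abg[:, None]
                - m_as[..., None]
                - m_bs[:, :, None, :]
                + m_ag[:, None, :, None]
                + m_bg[:, None, None, :]
                + m_s[..., None, None]
                - m_g[:, None, None, None]
            )
            ** 2
        )

        def F(num, den, dfn, dfd):
            return (num / dfn) / (den / dfd)

        expected = {
            "group": F(ss["group"], ss["subj"], k - 1, k * (n - 1)),
            "A": F(ss["A"], ss["errA"], a - 1, (a - 1) * k * (n - 1)),
            "A*group": F(ss["A*group"], ss["errA"], (a - 1) * (k - 1), (a - 1) * k * (n - 1)),
            "B": F(ss["B"], ss["errB"], b - 1, (b - 1) * k * (n - 1)),
            "B*group": F(ss["B*group"], ss["errB"], (b - 1) * (k - 1), (b - 1) * k * (n - 1)),
            "A*B": F(ss["A*B"], ss["errAB"], (a - 1) * (b - 1), (a - 1) * (b - 1) * k * (n - 1)),
            "A*B*group": F(
                ss["A*B*group"], ss["errAB"], (a - 1) * (b - 1) * (k - 1), (a - 1) * (b - 1) * k * (n - 1)
            ),
        }
        for eff, f_expected in expected.items():
            assert mine.F(eff) == pytest.approx(f_expected, rel=1e-10), eff


class TestInvariances:
    def test_relabeling_and_shift_leave_p_unchanged(self, rng):
        df = _long(rng, k=3, n=5, a=3)
        base = mixed_anova(df, dv="y", subject="subject", between="group", within="A")
        relabeled = df.copy()
        relabeled["A"] = relabeled["A"].map({"a0": "z", "a1": "q", "a2": "m"})
        relabeled["y"] = relabeled["y"] + 100.0
        again = mixed_anova(relabeled, dv="y", subject="subject", between="group", within="A")
        np.testing.assert_allclose(
            np.sort(base.table["p"].to_numpy()), np.sort(again.table["p"].to_numpy()), rtol=1e-9
        )

    def test_unbalanced_design_rejected(self, rng):
        df = _long(rng, k=2, n=4, a=2)
        df = df.iloc[:-1]  # drop one within-cell
        with pytest.raises(DegenerateDataError):
            mixed_anova(df, dv="y", subject="subject", between="group", within="A")


class TestTukey:
    def test_two_groups_reduce_to_t_test(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        tab = tukey_hsd({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert tab["q"][0] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-12)
        assert tab["p_adj"][0] == pytest.approx(p, rel=1e-6)

    def test_identical_means_give_p_near_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        tab = tukey_hsd({"a": base, "b": base + 1e-9, "c": base - 1e-9})
        assert (tab["p_adj"] > 0.9999).all()

    def test_three_groups_match_scipy(self, rng):
        g = [rng.normal(m, 1, 9) for m in (0.0, 0.8, 0.3)]
        mine = tukey_hsd({"a": g[0], "b": g[1], "c": g[2]})
        ref = sps.tukey_hsd(*g)
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for _, row in mine.iterrows():
            i, j = pairs[(row["group_a"], row["group_b"])]
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestOneSampleT:
    def test_symmetric_values_give_t_zero(self):
        res = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_df_structure(self, rng):
        res = one_sample_t(rng.normal(0, 1, 60), 0.0)
        assert res.df == 59

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([2.0, 2.0, 2.0], 0.0)
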