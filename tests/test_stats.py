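import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mozear.errors import InsufficientDataError, InvalidInputError
from mozear.stats import (
    FactorialData,
    art_anova,
    bonferroni,
    repeat_anova,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from oracles import enumerate_rank_sum_p, enumerate_signed_rank_p


def art_oracle(y, a, b):
    """Align-rank-ANOVA recipe recomputed via statsmodels OLS, independent
    of the package's sums-of-squares path."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    ma = {lv: y[a == lv].mean() for lv in np.unique(a)}
    mb = {lv: y[b == lv].mean() for lv in np.unique(b)}
    mab = {(i, j): y[(a == i) & (b == j)].mean()
           for i in np.unique(a) for j in np.unique(b)}
    ma_v = np.array([ma[x] for x in a])
    mb_v = np.array([mb[x] for x in b])
    mab_v = np.array([mab[(x, z)] for x, z in zip(a, b)])
    aligned = {
        "A": y - mab_v + ma_v - grand,
        "B": y - mab_v + mb_v - grand,
        "A:B": y - ma_v - mb_v + grand,
    }
    out = {}
    for eff, vals in aligned.items():
        ranks = sps.rankdata(vals)
        frame = pd.DataFrame({"r": ranks, "A": a, "B": b})
        model = smf.ols("r ~ C(A) * C(B)", data=frame).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        key = {"A": "C(A)", "B": "C(B)", "A:B": "C(A):C(B)"}[eff]
        out[eff] = (float(tab.loc[key, "F"]), float(tab.loc[key, "PR(>F)"]))
    return out


class TestArtAnova:
    def test_one_factor_reduces_to_rank_anova(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        (res,) = art_anova(FactorialData(y, {"group": g}))
        ranks = sps.rankdata(y)
        f_ref, p_ref = sps.f_oneway(*(ranks[g == lv] for lv in "abc"))
        assert res.statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_matches_direct_recipe_on_2x2(self):
        rng = np.random.default_rng(8)
        a = np.repeat(["a1", "a2"], 20)
        b = np.tile(np.repeat(["b1", "b2"], 10), 2)
        y = rng.normal(size=40) + 1.5 * (a == "a2")
        results = {r.effect: r for r in art_anova(FactorialData(y, {"A": a, "B": b}))}
        oracle = art_oracle(y, a, b)
        for eff in ("A", "B", "A:B"):
            assert results[eff].statistic == pytest.approx(oracle[eff][0], abs=1e-8)
            assert results[eff].p_value == pytest.approx(oracle[eff][1], abs=1e-8)
        assert results["A"].p_value < 0.01

    def test_matches_direct_recipe_unbalanced(self):
        rng = np.random.default_rng(12)
        a = np.array(["a1"] * 12 + ["a2"] * 16)
        b = np.array((["b1"] * 5 + ["b2"] * 7) + (["b1"] * 9 + ["b2"] * 7))
        y = rng.normal(size=28)
        results = {r.effect: r for r in art_anova(FactorialData(y, {"A": a, "B": b}))}
        oracle = art_oracle(y, a, b)
        for eff in ("A", "B", "A:B"):
            assert results[eff].statistic == pytest.approx(oracle[eff][0], abs=1e-8)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = np.repeat(["a1", "a2"], 12)
        b = np.tile(np.repeat(["b1", "b2"], 6), 2)
        y = rng.normal(size=24)
        r1 = art_anova(FactorialData(y, {"A": a, "B": b}))
        # strictly monotone transforms of aligned responses change cell
        # means, so only the one-factor design is exactly rank-invariant
        g = np.repeat(["u", "v", "w"], 8)
        one1 = art_anova(FactorialData(y, {"g": g}))[0]
        one2 = art_anova(FactorialData(np.exp(y / 2), {"g": g}))[0]
        assert one1.p_value == pytest.approx(one2.p_value, rel=1e-12)
        assert len(r1) == 3

    def test_constant_response_flagged(self):
        a = np.repeat(["a1", "a2"], 6)
        results = art_anova(FactorialData(np.ones(12), {"A": a}))
        assert all("degenerate" in r.flags for r in results)

    def test_empty_cell_rejected(self):
        a = np.array(["a1"] * 6 + ["a2"] * 6)
        b = np.array(["b1"] * 6 + ["b2"] * 6)  # a1xb2 and a2xb1 empty
        with pytest.raises(InvalidInputError):
            art_anova(FactorialData(np.arange(12.0), {"A": a, "B": b}))


class TestWilcoxonSignedRank:
    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]))
        assert res.p_value == pytest.approx(2 / 2**5)

    def test_identical_pairs_flagged(self):
        x = np.arange(6.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0 and "zero_variance" in res.flags

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_signed_rank(np.array([1.0]))

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = d[d != 0]
        if d.size < 2:
            d = np.array([0.4, -0.2, 0.7])
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)


class TestWilcoxonRankSum:
    def test_separated_groups_exact_p(self):
        res = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_near_null_center(self):
        x = np.arange(6.0)
        res = wilcoxon_rank_sum(x, x)
        assert res.p_value > 0.9

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_rank_sum(np.array([1.0]), np.array([2.0]))

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        nx, ny = rng.integers(2, 7), rng.integers(2, 7)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.5, 1, ny)
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-9)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.03]), [0.02, 0.06])
        np.testing.assert_allclose(bonferroni([0.9], m=3), [1.0])
        assert bonferroni([]).size == 0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(20)
        adj = bonferroni(p, m=7)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            bonferroni([0.5, 1.2])


def dct_frame(jo_shift=0.0, noise=0.0, n_repeats=7, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_repeats + 1):
        base = 6.0
        for tissue, shift in (("JO", jo_shift), ("head", 0.0), ("body", 0.0)):
            rows.append({"gene": "g1", "repeat": rep, "tissue": tissue,
                         "delta_ct": base + shift + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestRepeatAnova:
    def test_identical_tissues_give_null_result(self):
        res = repeat_anova(dct_frame())["g1"]
        omnibus = res[0]
        assert omnibus.statistic == pytest.approx(0.0)
        assert omnibus.p_value == pytest.approx(1.0)

    def test_large_effect_detected_and_agrees_with_paired_t(self):
        df = dct_frame(jo_shift=-2.0, noise=0.1, seed=3)
        res = repeat_anova(df)["g1"]
        contrasts = {r.effect: r for r in res[1:]}
        jo = contrasts["JO vs head"]
        assert jo.p_adjusted < 0.001
        wide = df.pivot(index="repeat", columns="tissue", values="delta_ct")
        t_ref = sps.ttest_rel(wide["JO"], wide["head"])
        assert jo.statistic == pytest.approx(t_ref.statistic, rel=1e-10)
        assert np.sign(jo.statistic) == -1.0

    def test_omnibus_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        df = dct_frame(jo_shift=-1.0, noise=0.5, seed=5)
        mine = repeat_anova(df)["g1"][0]
        ref = AnovaRM(df, depvar="delta_ct", subject="repeat",
                      within=["tissue"]).fit()
        assert mine.statistic == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-8)
        assert mine.p_value == pytest.approx(
            float(ref.anova_table["Pr > F"].iloc[0]), rel=1e-8)

    def test_single_repeat_rejected(self):
        with pytest.raises(InsufficientDataError):
            repeat_anova(dct_frame(n_repeats=1))

    def test_incomplete_repeat_dropped_with_warning(self):
        df = dct_frame(noise=0.2).query("not (repeat == 7 and tissue == 'JO')")
        with pytest.warns(UserWarning, match="incomplete"):
            res = repeat_anova(df)["g1"]
        assert res[0].n == 6
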