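"""Inferential procedures vs. independent oracles (brute force, scipy, statsmodels)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from simstress.inference import (
    paired_t,
    rm_anova,
    rm_anova_3x2,
    shapiro_wilk,
    wilcoxon_one_sample,
)


def brute_force_wilcoxon(values, mu0, alternative):
    """Exact signed-rank p by explicit enumeration of all 2^n sign patterns."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = d.size
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.asarray(signs, dtype=bool)].sum()
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
    total = 2**n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge / total, le / total))


class TestWilcoxon:
    def test_six_agreeing_ratings_one_sided(self):
        res = wilcoxon_one_sample([4] * 6, mu0=3, alternative="greater")
        assert res.p_value == pytest.approx(1 / 64)
        assert res.method == "exact"
        assert res.n_effective == 6

    def test_perfectly_symmetric_pair_two_sided(self):
        res = wilcoxon_one_sample([2, 4], mu0=3)
        assert res.p_value == 1.0

    def test_all_values_at_mu0_raise(self):
        with pytest.raises(ValueError, match="no information"):
            wilcoxon_one_sample([3, 3, 3], mu0=3)

    def test_statistic_bounds(self, rng):
        x = rng.normal(size=10)
        res = wilcoxon_one_sample(x, mu0=0)
        assert 0 <= res.w_statistic <= res.n_effective * (res.n_effective + 1) / 2

    def test_matches_scipy_exact_no_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            mine = wilcoxon_one_sample(x, mu0=0)
            ref = sps.wilcoxon(x, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_exact_equals_brute_force_enumeration_with_ties(self, values):
        if all(v == 3 for v in values):
            return
        for alternative in ("two_sided", "greater", "less"):
            mine = wilcoxon_one_sample(values, mu0=3, alternative=alternative)
            oracle = brute_force_wilcoxon(values, 3, alternative)
            assert mine.p_value == pytest.approx(oracle, abs=1e-12)

    def test_location_shift_monotonicity(self, rng):
        x = rng.normal(size=12)
        p_before = wilcoxon_one_sample(x, mu0=0, alternative="greater").p_value
        p_after = wilcoxon_one_sample(x + 1.0, mu0=0, alternative="greater").p_value
        assert p_after <= p_before + 1e-12

    def test_normal_approximation_close_to_exact_at_n25(self, rng):
        for _ in range(20):
            x = rng.normal(loc=0.3, size=25)
            exact = wilcoxon_one_sample(x, mu0=0, method="exact")
            approx = wilcoxon_one_sample(x, mu0=0, method="normal_approx")
            assert approx.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_pratt_zero_handling_differs_but_is_valid(self):
        res = wilcoxon_one_sample([3, 4, 4, 5, 2], mu0=3, zero_method="pratt")
        assert res.n_effective == 4
        assert 0 < res.p_value <= 1


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([1, 2, 3], [0, 0, 0])
        assert res.t == pytest.approx(2 / (1 / np.sqrt(3)))
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_df_is_n_minus_1(self, rng):
        res = paired_t(rng.normal(size=11), rng.normal(size=11))
        assert res.df == 10

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        mine = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_null_t_is_centred(self, rng):
        ts = [
            paired_t(rng.normal(size=8), rng.normal(size=8)).t for _ in range(300)
        ]
        assert abs(np.mean(ts)) < 0.15

    def test_zero_variance_differences_raise(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1, 2, 3], [0, 1, 2])


class TestRmAnova:
    def test_df_structure_matches_design(self, rng):
        res = rm_anova_3x2(rng.normal(size=(7, 3, 2)))
        assert res.df_pair("time") == (2, 12)
        assert res.df_pair("audition") == (1, 6)
        assert res.df_pair("time:audition") == (2, 12)

    def test_sum_of_squares_conservation(self, rng):
        y = rng.normal(size=(9, 3, 2))
        res = rm_anova(y)
        total = float(((y - y.mean()) ** 2).sum())
        assert res.table["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_ms_is_ss_over_df(self, rng):
        res = rm_anova(rng.normal(size=(5, 3, 2)))
        assert np.allclose(res.table["ms"], res.table["ss"] / res.table["df"])

    def test_matches_statsmodels_anova_rm(self, rng):
        y = rng.normal(size=(7, 3, 2))
        rows = [
            (i, f"t{j}", f"c{k}", y[i, j, k])
            for i in range(7) for j in range(3) for k in range(2)
        ]
        df = pd.DataFrame(rows, columns=["participant", "time", "audition", "value"])
        from statsmodels.stats.anova import AnovaRM

        ref = AnovaRM(df, "value", "participant", within=["time", "audition"]).fit()
        mine = rm_anova(df)
        for effect in ("time", "audition", "time:audition"):
            assert mine.f(effect) == pytest.approx(
                ref.anova_table.loc[effect, "F Value"], rel=1e-8
            )
            assert mine.p(effect) == pytest.approx(
                ref.anova_table.loc[effect, "Pr > F"], rel=1e-8
            )

    def test_two_level_no_second_factor_equals_paired_t_squared(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        res = rm_anova(np.stack([a, b], axis=1)[:, :, None])
        t = paired_t(a, b)
        assert res.f("time") == pytest.approx(t.t**2, rel=1e-8)
        assert res.p("time") == pytest.approx(t.p_value, rel=1e-8)

    def test_degenerate_identical_cells_flagged(self):
        with pytest.warns(UserWarning, match="zero error variance"):
            res = rm_anova(np.ones((4, 3, 2)))
        assert np.isnan(res.f("time"))
        assert res.table["ss"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_long_input_rejected(self):
        df = pd.DataFrame(
            {
                "participant": [1, 1, 1, 2, 2],
                "time": ["a", "b", "c", "a", "b"],
                "audition": ["x"] * 5,
                "value": [1.0, 2, 3, 4, 5],
            }
        )
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df)

    def test_gg_correction_only_shrinks_significance(self, rng):
        y = rng.normal(size=(7, 3, 2))
        plain = rm_anova(y)
        gg = rm_anova(y, sphericity_correction="gg")
        for effect in ("time", "time:audition"):
            assert gg.p(effect) >= plain.p(effect) - 1e-12


class TestShapiroWilk:
    def test_bimodal_sample_rejected(self):
        x = np.array([0.0] * 10 + [10.0] * 10) + np.linspace(0, 1e-3, 20)
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_normal_quantile_grid_has_high_w(self):
        grid = sps.norm.ppf((np.arange(1, 11) - 0.5) / 10)
        w, _ = shapiro_wilk(grid)
        assert w > 0.98

    def test_gaussian_calibration(self, rng):
        kept = sum(
            shapiro_wilk(rng.normal(size=50))[1] > 0.05 for _ in range(1000)
        )
        assert kept >= 900

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])
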