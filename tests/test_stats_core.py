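"""Statistics core: ANOVA decompositions, Tukey HSD, BH, Welch t."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from suppscreen.stats_core import (
    StatsError,
    bh_adjust,
    one_way_anova,
    significance_stars,
    tukey_hsd,
    two_way_anova,
    welch_t,
)


class TestOneWayAnova:
    def test_hand_decomposed_fixture(self):
        table = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert table.loc["between", "sum_sq"] == pytest.approx(6.0)
        assert table.loc["within", "sum_sq"] == pytest.approx(6.0)
        assert table.loc["between", "F"] == pytest.approx(3.0)

    def test_identical_groups_null(self):
        table = one_way_anova([[1, 2, 3]] * 3)
        assert table.loc["between", "F"] == 0.0
        assert table.loc["between", "p"] == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        table = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert table.loc["between", "F"] == pytest.approx(t**2, rel=1e-9)
        assert table.loc["between", "p"] == pytest.approx(p, rel=1e-9)

    def test_sum_of_squares_conserved(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 5) for m in (0, 1, 2, 5)]
        table = one_way_anova(groups)
        total = np.concatenate(groups)
        assert table.loc["total", "sum_sq"] == pytest.approx(
            ((total - total.mean()) ** 2).sum(), rel=1e-9
        )

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova([[1.0], [2.0, 3.0]])


def _balanced(a_levels, b_levels, n, rng, effects=None):
    rows = []
    for a in a_levels:
        for b in b_levels:
            mu = (effects or {}).get((a, b), 0.0)
            for v in rng.normal(mu, 1.0, n):
                rows.append({"a": a, "b": b, "value": v})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_all_cells_equal_gives_zero_f(self):
        data = pd.DataFrame(
            {"a": ["x", "x", "y", "y"] * 2, "b": ["u", "v"] * 4, "value": 1.0}
        )
        table = two_way_anova(data, "a", "b", "value")
        assert (table.loc[["a", "b", "interaction"], "F"] == 0).all()
        assert (table.loc[["a", "b", "interaction"], "p"] == 1).all()

    def test_additive_effects_have_no_interaction(self):
        rng = np.random.default_rng(0)
        effects = {("x", "u"): 0.0, ("x", "v"): 1.0, ("y", "u"): 2.0, ("y", "v"): 3.0}
        data = _balanced("xy", "uv", 500, rng, effects)
        table = two_way_anova(data, "a", "b", "value")
        assert table.loc["a", "p"] < 1e-6
        assert table.loc["b", "p"] < 1e-6
        assert table.loc["interaction", "p"] > 0.01

    def test_matches_statsmodels_ols_decomposition(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        data = _balanced("xyz", "uv", 4, rng, {("x", "u"): 1.0, ("z", "v"): -0.5})
        ours = two_way_anova(data, "a", "b", "value")
        fit = smf.ols("value ~ C(a) * C(b)", data=data).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.loc["a", "sum_sq"] == pytest.approx(ref.loc["C(a)", "sum_sq"])
        assert ours.loc["b", "sum_sq"] == pytest.approx(ref.loc["C(b)", "sum_sq"])
        assert ours.loc["interaction", "F"] == pytest.approx(ref.loc["C(a):C(b)", "F"])
        assert ours.loc["interaction", "p"] == pytest.approx(
            ref.loc["C(a):C(b)", "PR(>F)"]
        )

    def test_unbalanced_design_is_a_hard_error(self):
        rng = np.random.default_rng(1)
        data = _balanced("xy", "uv", 3, rng).drop(index=0)
        with pytest.raises(StatsError, match="unbalanced"):
            two_way_anova(data, "a", "b", "value")

    def test_missing_cell_is_an_error(self):
        rng = np.random.default_rng(1)
        data = _balanced("xy", "uv", 3, rng)
        data = data[~((data["a"] == "x") & (data["b"] == "v"))]
        with pytest.raises(StatsError, match="missing cell"):
            two_way_anova(data, "a", "b", "value")


class TestTukey:
    def test_two_groups_match_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        (comp,) = tukey_hsd([a, b])
        _, p = sps.ttest_ind(a, b)  # pooled-variance t
        assert comp.p_adjusted == pytest.approx(p, rel=1e-9)

    def test_identical_means_not_significant(self):
        comps = tukey_hsd([[1.0, 2, 3]] * 3)
        assert all(c.p_adjusted > 0.99 and c.stars == "ns" for c in comps)

    def test_far_shifted_group_stars(self):
        rng = np.random.default_rng(6)
        near1 = rng.normal(0, 1, 6)
        near2 = rng.normal(0, 1, 6)
        far = rng.normal(10, 1, 6)  # ten s.d. away
        comps = {
            (c.group_a, c.group_b): c
            for c in tukey_hsd([near1, near2, far], labels=["n1", "n2", "far"])
        }
        assert comps[("n1", "far")].stars == "***"
        assert comps[("n2", "far")].stars == "***"
        assert comps[("n1", "n2")].stars == "ns"

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.8, 1.6)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for comp in ours:
            i = int(comp.group_a[-1])
            j = int(comp.group_b[-1])
            assert comp.p_adjusted == pytest.approx(ref.pvalue[i, j], abs=1e-8)


class TestBHAdjust:
    def test_step_up_collapse(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30)
    )
    def test_never_decreasing_capped_and_order_preserving(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # adjustment is a monotone transform of the raw ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestWelch:
    def test_identical_samples_null(self):
        res = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_balanced_equal_variance_matches_pooled(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 8)
        b = a + 0.8  # identical sample variance, equal n -> Welch df = 2n-2
        res = welch_t(a, b)
        t, p = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(t, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_planted_shift_detected(self):
        res = welch_t([0.0, 0.1, -0.1], [5.0, 5.1, 4.9])
        assert res.p < 0.05

    def test_short_input_rejected(self):
        with pytest.raises(StatsError):
            welch_t([1.0], [1.0, 2.0])


def test_star_thresholds():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.2)] == [
        "***",
        "**",
        "*",
        "ns",
    ]
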