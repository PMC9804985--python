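"""Statistics: transform, assumption gates, Dunnett, cohort workflow.

Frozen reference values were computed independently with R 4.3
(``bartlett.test``, ``shapiro.test``, ``multcomp::glht`` with the
single-step Dunnett adjustment).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from isletquant.stats import (
    check_assumptions,
    compare_cohort,
    dunnett_test,
    log10_transform,
    results_to_frame,
)


class TestLog10Transform:
    def test_powers_of_ten(self):
        assert np.allclose(log10_transform([1, 10, 100]), [0, 1, 2])

    def test_fractional_value(self):
        assert log10_transform([0.3])[0] == pytest.approx(-0.5229, abs=1e-4)

    def test_zero_raises_naming_the_animal(self):
        with pytest.raises(ValueError, match="cat7"):
            log10_transform([1.0, 0.0], ids=["cat1", "cat7"])

    def test_offset_option_rescues_zeros(self):
        out = log10_transform([0.0, 9.0], offset=1.0)
        assert np.allclose(out, [0.0, 1.0])

    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_inverts_through_exponentiation(self, values):
        out = log10_transform(values)
        assert np.allclose(10.0**out, values, rtol=1e-12)


class TestAssumptionChecks:
    def test_identical_variances_give_bartlett_stat_zero(self):
        check = check_assumptions({"a": [1, 2, 3, 4, 5],
                                   "b": [11, 12, 13, 14, 15]})
        assert check.bartlett_stat == pytest.approx(0.0, abs=1e-12)
        assert check.bartlett_p == pytest.approx(1.0, abs=1e-12)

    def test_bartlett_matches_r_reference(self):
        # R: bartlett.test(list(1:5, c(2,4,6,8,10)))
        check = check_assumptions({"a": [1, 2, 3, 4, 5],
                                   "b": [2, 4, 6, 8, 10]})
        assert check.bartlett_stat == pytest.approx(1.5867985871, abs=1e-6)
        assert check.bartlett_p == pytest.approx(0.2077841233, abs=1e-6)

    def test_shapiro_matches_r_reference(self):
        # R: shapiro.test(1:8) and a right-skewed vector
        check = check_assumptions({"a": [1, 2, 3, 4, 5, 6, 7, 8],
                                   "b": [0.1, 2.3, 2.5, 2.6, 5.9, 3.1, 2.2,
                                         2.45, 2.8, 9.9]})
        assert check.shapiro_w["a"] == pytest.approx(0.9748582563, abs=1e-4)
        assert check.shapiro_p["a"] == pytest.approx(0.9331651916, abs=1e-4)
        assert check.shapiro_p["b"] == pytest.approx(0.0059610719, abs=1e-4)
        assert not check.passed  # group b fails normality

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="n=2"):
            check_assumptions({"a": [1, 2], "b": [1, 2, 3]})


class TestDunnett:
    def test_treatment_identical_to_control_gives_t0_p1(self):
        res = dunnett_test([1.0, 2.0, 3.0, 4.0], [[1.0, 2.0, 3.0, 4.0]])[0]
        assert res.t_value == 0.0
        assert res.p_adjusted == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_single_treatment_equals_pooled_t_test(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(0, 1, int(rng.integers(4, 12)))
        t = rng.normal(0.4, 1, int(rng.integers(4, 12)))
        res = dunnett_test(c, [t])[0]
        df = len(c) + len(t) - 2
        sp2 = (((c - c.mean()) ** 2).sum() + ((t - t.mean()) ** 2).sum()) / df
        t_ref = (t.mean() - c.mean()) / np.sqrt(sp2 * (1 / len(c) + 1 / len(t)))
        p_ref = 2 * sps.t.sf(abs(t_ref), df)
        assert res.t_value == pytest.approx(t_ref, abs=1e-12)
        assert res.p_adjusted == pytest.approx(p_ref, abs=1e-8)

    def test_two_treatments_match_r_multcomp(self):
        # R: summary(glht(aov(y~g), mcp(g="Dunnett")), adjusted("single-step"))
        ctrl = [1.1, 2.3, 1.9, 2.5]
        t1 = [2.0, 2.8, 3.1, 2.4, 2.9]
        t2 = [0.9, 1.2, 1.8, 1.4]
        res = dunnett_test(ctrl, [t1, t2], names=["t1", "t2"])
        expected = {
            "t1": (0.69, 0.32515765, 2.12204754, 0.10358179),
            "t2": (-0.625, 0.34274626, -1.82350639, 0.16648955),
        }
        for r in res:
            diff, se, t, p = expected[r.treatment]
            assert r.diff == pytest.approx(diff, abs=1e-8)
            assert r.se == pytest.approx(se, abs=1e-8)
            assert r.t_value == pytest.approx(t, abs=1e-6)
            assert r.p_adjusted == pytest.approx(p, abs=5e-4)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(42)
        c = rng.normal(0, 1, 8)
        t1 = rng.normal(0.7, 1, 6)
        t2 = rng.normal(-0.3, 1, 7)
        ours = dunnett_test(c, [t1, t2])
        ref = sps.dunnett(t1, t2, control=c, alternative="two-sided",
                          random_state=0)
        assert np.allclose([r.p_adjusted for r in ours], ref.pvalue, atol=2e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_adjusted_p_dominates_unadjusted(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(0, 1, 7)
        groups = [rng.normal(0.3, 1, 6) for _ in range(3)]
        res = dunnett_test(c, groups)
        for r in res:
            p_unadj = 2 * sps.t.sf(abs(r.t_value), r.df)
            assert r.p_adjusted >= p_unadj - 1e-12

    def test_monte_carlo_method_agrees_with_quadrature(self):
        rng = np.random.default_rng(3)
        c = rng.normal(0, 1, 8)
        groups = [rng.normal(0.5, 1, 7) for _ in range(2)]
        quad = dunnett_test(c, groups, method="quadrature")
        mc = dunnett_test(c, groups, method="mc",
                          rng=np.random.default_rng(1), n_mc_draws=400_000)
        for a, b in zip(quad, mc):
            assert b.p_adjusted == pytest.approx(a.p_adjusted, abs=0.01)

    def test_scale_shift_invariance_of_p_value(self):
        rng = np.random.default_rng(5)
        c = rng.normal(0, 1, 6)
        t = rng.normal(1, 1, 6)
        base = dunnett_test(c, [t])[0]
        moved = dunnett_test(3.5 * c + 10, [3.5 * t + 10])[0]
        assert moved.t_value == pytest.approx(base.t_value, rel=1e-12)
        assert moved.p_adjusted == pytest.approx(base.p_adjusted, abs=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="treatment"):
            dunnett_test([1, 2, 3], [])
        with pytest.raises(ValueError, match="n >= 2"):
            dunnett_test([1.0], [[1, 2]])
        with pytest.raises(ValueError, match="variance"):
            dunnett_test([2.0, 2.0], [[3.0, 3.0]])


class TestCompareCohort:
    @staticmethod
    def cohort(seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n, mu in [("non_diabetic", 10, 1.0), ("diabetic", 9, 1.0 + shift)]:
            for i in range(n):
                rows.append({"animal_id": f"{g}_{i}", "group": g,
                             "islet_area_pct_of_tissue":
                                 float(10 ** rng.normal(mu, 0.2))})
        return pd.DataFrame(rows)

    def test_animal_order_permutation_leaves_results_unchanged(self):
        table = self.cohort(seed=1)
        a = compare_cohort(table, ["islet_area_pct_of_tissue"],
                           control="non_diabetic")[0]
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        b = compare_cohort(shuffled, ["islet_area_pct_of_tissue"],
                           control="non_diabetic")[0]
        assert a.comparisons == b.comparisons
        assert a.groups == b.groups
        assert a.bartlett_p == b.bartlett_p

    def test_raw_scale_summaries_are_mean_and_sd(self):
        table = self.cohort(seed=2)
        res = compare_cohort(table, ["islet_area_pct_of_tissue"],
                             control="non_diabetic")[0]
        sub = table[table.group == "diabetic"]["islet_area_pct_of_tissue"]
        summary = {g.name: g for g in res.groups}["diabetic"]
        assert summary.raw_mean == pytest.approx(sub.mean())
        assert summary.raw_sd == pytest.approx(sub.std(ddof=1))

    def test_zero_policy_error_and_exclude(self):
        table = self.cohort(seed=3)
        table.loc[0, "islet_area_pct_of_tissue"] = 0.0
        with pytest.raises(ValueError, match="non_diabetic_0"):
            compare_cohort(table, ["islet_area_pct_of_tissue"],
                           control="non_diabetic")
        res = compare_cohort(table, ["islet_area_pct_of_tissue"],
                             control="non_diabetic", zero_policy="exclude")[0]
        assert {g.name: g.n for g in res.groups}["non_diabetic"] == 9
        assert any("non_diabetic_0" in n for n in res.notes)

    def test_metric_missing_for_whole_group_is_skipped(self, caplog):
        table = self.cohort(seed=4)
        table.loc[table.group == "diabetic",
                  "islet_area_pct_of_tissue"] = np.nan
        res = compare_cohort(table, ["islet_area_pct_of_tissue"],
                             control="non_diabetic")
        assert res == []

    def test_unknown_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            compare_cohort(self.cohort(), ["islet_area_pct_of_tissue"],
                           control="nope")

    def test_results_frame_has_one_row_per_comparison(self):
        res = compare_cohort(self.cohort(seed=6),
                             ["islet_area_pct_of_tissue"],
                             control="non_diabetic")
        frame = results_to_frame(res)
        assert len(frame) == 1
        assert {"metric", "t_value", "p_adjusted", "bartlett_p"} <= \
            set(frame.columns)
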