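"""Toxicity bracketing and group statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from xenoscreen import (
    ToxicityTable,
    anova_dunnett,
    group_summary,
    ld50_bracket,
    max_safe_concentration,
    two_sample_t,
)
from xenoscreen.datasets import reference_survival_table

CONC = np.array([0.125, 0.25, 0.5, 1, 2.5, 5, 10])


class TestLd50Bracket:
    def test_full_survival_brackets_above_highest_dose(self):
        br = ld50_bracket("imatinib", CONC, [100] * 7)
        assert (br.lower_um, br.upper_um) == (10.0, math.inf)

    def test_sharp_dropoff_brackets_the_crossing(self):
        br = ld50_bracket("niclosamide", CONC, [100, 100, 100, 0, 0, 0, 0])
        assert (br.lower_um, br.upper_um) == (0.5, 1.0)

    def test_death_at_lowest_dose(self):
        br = ld50_bracket("x", CONC, [0] * 7)
        assert (br.lower_um, br.upper_um) == (0.0, 0.125)

    def test_non_monotone_row_warns_and_uses_first_crossing(self):
        with pytest.warns(UserWarning, match="recovers"):
            br = ld50_bracket("odd", CONC, [100, 100, 0, 100, 0, 0, 0])
        assert (br.lower_um, br.upper_um) == (0.25, 0.5)

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            surv = rng.choice([0.0, 100.0], size=7)
            # oracle: exhaustive scan at the first sub-50% concentration
            crossing = [j for j in range(7) if surv[j] < 50]
            if not crossing:
                expected = (10.0, math.inf)
            else:
                j = crossing[0]
                expected = (CONC[j - 1] if j else 0.0, CONC[j])
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                br = ld50_bracket("r", CONC, surv)
            assert (br.lower_um, br.upper_um) == expected


class TestMaxSafeConcentration:
    def test_reference_table_selects_half_micromolar(self):
        assert max_safe_concentration(reference_survival_table()) == 0.5

    def test_all_rows_full_survival_selects_highest_dose(self):
        table = ToxicityTable(["a", "b"], CONC, np.full((2, 7), 100.0))
        assert max_safe_concentration(table) == 10.0

    def test_agrees_with_exhaustive_scan_on_random_tables(self):
        rng = np.random.default_rng(777)
        for _ in range(300):
            surv = rng.choice([0.0, 100.0], size=(4, 7), p=[0.3, 0.7])
            table = ToxicityTable(list("abcd"), CONC, surv)
            safe = [j for j in range(7) if (surv[:, j] == 100).all()]
            if safe:
                assert max_safe_concentration(table) == CONC[max(safe)]
            else:
                with pytest.raises(ValueError, match="no common safe"):
                    max_safe_concentration(table)

    def test_malformed_cell_named_in_error(self):
        import pandas as pd

        df = pd.DataFrame({"compound": ["a"], "0.5": ["oops"]})
        with pytest.raises(ValueError, match="compound='a'.*0.5"):
            ToxicityTable.from_dataframe(df)


class TestTwoSampleT:
    def test_identical_groups_give_zero_t_unit_p(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        expected_t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 4), rel=1e-12)

    def test_anova_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=9), rng.normal(1, 1, size=7)
        t, _ = two_sample_t(a, b)
        f, _ = sps.f_oneway(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestGroupSummary:
    def test_constant_group(self):
        assert group_summary([2, 2, 2]) == (2.0, 0.0)

    def test_hand_computed_sem(self):
        mean, sem = group_summary([1, 2, 3])
        assert mean == 2.0
        assert sem == pytest.approx(1 / math.sqrt(3))

    def test_scaling_scales_both(self):
        m1, s1 = group_summary([1.0, 2.0, 4.0])
        m2, s2 = group_summary([3.0, 6.0, 12.0])
        assert (m2, s2) == pytest.approx((3 * m1, 3 * s1))

    def test_single_observation_has_no_sem(self):
        assert group_summary([5.0]) == (5.0, None)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestAnovaDunnett:
    def test_two_groups_reduce_to_students_t(self):
        rng = np.random.default_rng(21)
        groups = {"ctrl": rng.normal(size=10), "drug": rng.normal(0.8, 1, size=10)}
        comp = anova_dunnett(groups, "ctrl")
        _, p_t = two_sample_t(groups["ctrl"], groups["drug"])
        p_adj = comp.comparisons["p_adjusted"].iloc[0]
        assert p_adj == pytest.approx(p_t, abs=1e-3)

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(22)
        groups = {"c": rng.normal(size=8)} | {
            f"g{i}": rng.normal(0.3 * i, 1, size=8) for i in range(1, 5)
        }
        comp = anova_dunnett(groups, "c")
        assert (comp.comparisons["p_adjusted"] >= comp.comparisons["p_raw"] - 1e-12).all()

    def test_location_shift_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(23)
        groups = {"c": rng.normal(size=6), "a": rng.normal(size=6), "b": rng.normal(1, 1, 6)}
        shifted = {g: v + 100.0 for g, v in groups.items()}
        c1 = anova_dunnett(groups, "c", seed=0)
        c2 = anova_dunnett(shifted, "c", seed=0)
        assert c1.statistic == pytest.approx(c2.statistic)
        assert c1.comparisons["statistic"].to_numpy() == pytest.approx(
            c2.comparisons["statistic"].to_numpy()
        )

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(24)
        groups = {"c": rng.normal(size=12), "a": rng.normal(0.5, 1, 12), "b": rng.normal(1, 1, 12)}
        p1 = anova_dunnett(groups, "c", seed=7).comparisons["p_adjusted"].to_numpy()
        p2 = anova_dunnett(groups, "c", seed=7).comparisons["p_adjusted"].to_numpy()
        assert np.array_equal(p1, p2)

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_dunnett({"c": [1.0, 1.0], "a": [2.0, 2.0]}, "c")

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            anova_dunnett({"a": [1.0, 2.0], "b": [2.0, 3.0]}, "ctrl")

    def test_summary_table_layout(self):
        rng = np.random.default_rng(25)
        groups = {"c": rng.normal(size=5), "a": rng.normal(size=5)}
        table = anova_dunnett(groups, "c").summary()
        assert set(table["group"]) == {"c", "a"}
        assert {"n", "mean", "sem", "p_adjusted"} <= set(table.columns)
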