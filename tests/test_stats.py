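"""Cohort statistics: chi-square, Mann-Whitney, Spearman, t-tests, BMI z."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from qeeg.stats import (
    BmiNormTable,
    bmi_zscore,
    chi_square_2x2,
    classify_weight,
    cohort_compare,
    independent_ttest,
    mann_whitney,
    per_frequency_ttest,
    spearman,
    spearman_p_from_rho,
    synthetic_norm_table,
)


class TestBmiZ:
    def test_arithmetic(self):
        norms = BmiNormTable(pd.DataFrame(
            [("M", 10, 20, 21.0, 3.0)], columns=BmiNormTable.COLUMNS))
        assert bmi_zscore(21.0, 15, "M", norms) == 0.0
        assert bmi_zscore(27.0, 15, "M", norms) == pytest.approx(2.0)
        assert bmi_zscore(25.5, 15, "M", norms) == pytest.approx(1.5)

    def test_affine_equivariance(self):
        base = pd.DataFrame([("F", 0, 99, 20.0, 2.5)], columns=BmiNormTable.COLUMNS)
        shifted = base.copy()
        shifted["mean"] += 1.7
        z0 = bmi_zscore(24.0, 30, "F", BmiNormTable(base))
        z1 = bmi_zscore(24.0, 30, "F", BmiNormTable(shifted))
        assert z1 - z0 == pytest.approx(-1.7 / 2.5)

    def test_uncovered_band_errors(self):
        norms = synthetic_norm_table()
        with pytest.raises(ValueError, match="no norm band"):
            norms.lookup("M", 120)

    @pytest.mark.parametrize("z,expected", [
        (1.0, "normal"),    # strict inequality at the cutoff
        (1.5, "overweight"),
        (2.0, "overweight"),
        (2.5, "obese"),
        (-0.3, "normal"),
    ])
    def test_weight_classification(self, z, expected):
        assert classify_weight(z) == expected


class TestChiSquare:
    @pytest.mark.parametrize("table,p3dp", [
        ([[4, 6], [5, 5]], 0.653),   # sex split of a 10 + 10 cohort
        ([[7, 3], [4, 6]], 0.178),   # overweight/obesity split
    ])
    def test_reference_two_by_two_pvalues(self, table, p3dp):
        res = chi_square_2x2(table)
        assert round(res.p_value, 3) == p3dp

    def test_closed_form_identity(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 30, 4)
            res = chi_square_2x2([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(closed, abs=1e-12)

    def test_proportional_rows_independent(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_margin_degenerate(self):
        with pytest.raises(ValueError, match="degenerate table"):
            chi_square_2x2([[0, 5], [0, 5]])

    def test_yates_correction_flag_changes_statistic(self):
        plain = chi_square_2x2([[4, 6], [5, 5]])
        yates = chi_square_2x2([[4, 6], [5, 5]], correction=True)
        assert yates.statistic < plain.statistic


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sstats.rankdata(pooled)[:n1].sum() - n1 * (n1 + 1) / 2
    ranks = sstats.rankdata(pooled)
    us = [
        sum(ranks[list(c)]) - n1 * (n1 + 1) / 2
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.asarray(us)
    mean_u = n1 * len(b) / 2
    return min(1.0, np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_under_swap(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(6) + 0.5
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(b, a).p_value, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 7), st.integers(3, 7))
    @settings(max_examples=40, deadline=None)
    def test_exact_mode_matches_full_enumeration(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n1)
        b = rng.standard_normal(n2) + rng.uniform(-1, 1)
        res = mann_whitney(a, b, mode="exact")
        assert res.p_value == pytest.approx(brute_force_mw_p(a, b), abs=1e-9)

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 1, 2, 3], [2, 4, 4, 5])
        assert "asymptotic" in res.method
        assert 0 <= res.p_value <= 1

    def test_rank_invariance_under_positive_scaling(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 1
        assert mann_whitney(3.7 * a, 3.7 * b).p_value == pytest.approx(
            mann_whitney(a, b).p_value, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            mann_whitney([], [1.0])


class TestSpearman:
    @pytest.mark.parametrize("rho,p3dp", [
        (0.547, 0.013),
        (0.524, 0.018),
        (0.534, 0.015),
        (0.329, 0.157),
    ])
    def test_rho_to_p_conversion_n20(self, rho, p3dp):
        assert round(spearman_p_from_rho(rho, 20), 3) == p3dp

    def test_monotone_transform_gives_rho_one(self):
        x = np.arange(1, 11, dtype=float)
        res = spearman(x, x**3)
        assert res.statistic == pytest.approx(1.0)

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        r0 = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(r0, abs=1e-12)
        assert spearman(x, 2 * y + 5).statistic == pytest.approx(r0, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        res = spearman(x, y)
        ref = sstats.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_permutation_option_close_to_t_for_moderate_n(self, rng):
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12)
        pt = spearman(x, y, method="t").p_value
        pp = spearman(x, y, method="permutation").p_value
        assert pp == pytest.approx(pt, abs=0.05)


class TestTTests:
    def test_identical_groups_p_one(self):
        a = np.array([[0.1, 0.5], [0.2, 0.4], [0.3, 0.3]])
        df = per_frequency_ttest(a, a)
        assert np.allclose(df["t"], 0.0)
        assert np.allclose(df["p"], 1.0)

    def test_zero_pooled_variance_flagged_degenerate(self):
        df = per_frequency_ttest([[0.0], [0.0]], [[1.0], [1.0]])
        assert bool(df["degenerate"][0])
        assert np.isnan(df["p"][0])

    def test_welch_flag_matches_scipy(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(12) * 3 + 1
        res = independent_ttest(a, b, variant="welch")
        ref = sstats.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_bh_annotation_monotone(self, rng):
        a = rng.standard_normal((5, 10))
        b = rng.standard_normal((5, 10)) + 0.5
        df = per_frequency_ttest(a, b, bh_annotation=True)
        assert np.all(df["p_bh"] >= df["p"] - 1e-12)
        assert np.all(df["p_bh"] <= 1.0)


class TestCohortCompare:
    def _cohort(self, rng, mirror=False):
        rows = []
        for g, n in (("PWS", 8), ("control", 8)):
            for i in range(n):
                z = rng.normal(1.0, 0.8)
                rows.append({
                    "participant_id": f"{g}{i}", "group": g,
                    "age": rng.uniform(10, 30), "sex": "M" if i % 2 else "F",
                    "genotype": "deletion" if g == "PWS" else "NA",
                    "intelligence": 2 if (g == "PWS" and i < 5) else 0,
                    "bmi": rng.uniform(18, 30), "bmi_z": z,
                    "weight_class": "normal",
                    "cpt_omission": rng.normal(60 if g == "PWS" else 50, 5),
                })
        df = pd.DataFrame(rows)
        if mirror:  # make control a copy of PWS on continuous variables
            cont = ["age", "bmi", "bmi_z", "cpt_omission"]
            df.loc[df.group == "control", cont] = df.loc[df.group == "PWS", cont].values
            df.loc[df.group == "control", "sex"] = df.loc[df.group == "PWS", "sex"].values
        return df

    def test_mirrored_groups_show_no_differences(self, rng):
        tabs = cohort_compare(self._cohort(rng, mirror=True))
        demo = tabs["demographics"].set_index("variable")
        for var in ("Age (years)", "BMI", "BMI z-score"):
            assert demo.loc[var, "p"] == pytest.approx(1.0)
        assert demo.loc["Sex (M/F)", "statistic"] == pytest.approx(0.0)
        assert tabs["cpt"]["p"].iloc[0] == pytest.approx(1.0)

    def test_scaling_a_variable_keeps_mw_p(self, rng):
        df = self._cohort(rng)
        p0 = cohort_compare(df)["cpt"]["p"].iloc[0]
        df["cpt_omission"] *= 123.0
        assert cohort_compare(df)["cpt"]["p"].iloc[0] == pytest.approx(p0, abs=1e-12)

    def test_empty_group_rejected(self, rng):
        df = self._cohort(rng)
        with pytest.raises(ValueError, match="non-empty"):
            cohort_compare(df[df.group == "PWS"])
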