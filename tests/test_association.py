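"""Association module: odds ratios, chi-square tests, HWE, tabulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lmp2ms import (
    CaseControlAssociation,
    GenotypeSimConfig,
    cohort_homogeneity,
    hwe_test,
    monte_carlo_chi2,
    odds_ratio,
    onset_age_compare,
    pearson_chi2,
    simulate_population,
    tabulate,
)
from lmp2ms.association import SubjectRecord
from lmp2ms.exceptions import InsufficientDataError, ParameterError


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected_or, expected_ci",
        [
            ((26, 165, 32, 90), 0.443, (0.249, 0.790)),  # HH vs RR
            ((26, 146, 32, 80), 0.445, (0.248, 0.799)),  # HH vs RH
            ((146, 165, 80, 90), 0.995, (0.684, 1.448)),  # RH vs RR
        ],
    )
    def test_published_female_a02_contrasts(self, cells, expected_or, expected_ci):
        res = odds_ratio(*cells)
        assert round(res.odds_ratio, 3) == expected_or
        assert (round(res.ci95[0], 3), round(res.ci95[1], 3)) == expected_ci

    def test_symmetric_table_is_null(self):
        res = odds_ratio(10, 10, 10, 10)
        assert res.odds_ratio == 1.0
        lo, hi = res.ci95
        assert math.isclose(math.log(lo), -math.log(hi), rel_tol=1e-12)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(max_examples=50, derandomize=True)
    def test_label_swap_reciprocity(self, cells):
        a, b, c, d = cells
        assert math.isclose(
            odds_ratio(a, b, c, d).odds_ratio * odds_ratio(b, a, d, c).odds_ratio,
            1.0, rel_tol=1e-12,
        )

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio(0, 10, 5, 10)
        assert res.haldane_corrected
        assert res.odds_ratio == (0.5 * 10.5) / (10.5 * 5.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            odds_ratio(-1, 2, 3, 4)


class TestPearsonChi2:
    def test_published_overall_and_pairwise_p_values(self, table2_counts):
        res = pearson_chi2(table2_counts.to_numpy())
        assert res.df == 2
        assert round(res.p_asymptotic, 3) == 0.013
        pairwise = {
            ("HH", "RR"): 0.005,
            ("HH", "RH"): 0.006,
            ("RH", "RR"): 0.981,
        }
        for (g1, g2), expected in pairwise.items():
            sub = table2_counts[[g1, g2]].to_numpy()
            assert round(pearson_chi2(sub).p_asymptotic, 3) == expected

    def test_uniform_table_has_zero_statistic(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.p_asymptotic == 1.0

    @given(st.lists(st.tuples(st.integers(1, 50), st.integers(1, 50),
                              st.integers(1, 50)), min_size=2, max_size=4))
    @settings(max_examples=30, derandomize=True)
    def test_transpose_invariance(self, rows):
        table = np.array(rows)
        assert math.isclose(
            pearson_chi2(table).chi2, pearson_chi2(table.T).chi2, rel_tol=1e-10
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            pearson_chi2([[0, 0], [5, 3]])


class TestMonteCarloChi2:
    def test_converges_to_asymptotic_p(self, table2_counts):
        res = monte_carlo_chi2(table2_counts.to_numpy(), n_reps=20_000, seed=7)
        assert abs(res.p_monte_carlo - 0.013) <= 3 * res.mc_stderr

    def test_matches_fixed_margin_enumeration_2x2(self):
        # independent oracle: enumerate all 2x2 tables with the observed
        # margins, weighting by the hypergeometric conditional null
        table = np.array([[3, 7], [8, 2]])
        row, col = table.sum(axis=1), table.sum(axis=0)
        n = table.sum()
        expected = np.outer(row, col) / n
        obs_chi2 = ((table - expected) ** 2 / expected).sum()
        p_exact = 0.0
        for a in range(max(0, row[0] - col[1]), min(row[0], col[0]) + 1):
            t = np.array([[a, row[0] - a], [col[0] - a, row[1] - col[0] + a]])
            chi2 = ((t - expected) ** 2 / expected).sum()
            if chi2 >= obs_chi2 - 1e-9:
                p_exact += stats.hypergeom.pmf(a, n, row[0], col[0])
        res = monte_carlo_chi2(table, n_reps=20_000, seed=11)
        assert abs(res.p_monte_carlo - p_exact) <= 3 * max(res.mc_stderr, 1e-4)

    def test_single_column_table_is_null(self):
        res = monte_carlo_chi2(np.array([[5], [9]]), n_reps=1000, seed=0)
        assert res.p_monte_carlo == 1.0

    def test_deterministic_given_seed(self, table2_counts):
        a = monte_carlo_chi2(table2_counts.to_numpy(), n_reps=2000, seed=3)
        b = monte_carlo_chi2(table2_counts.to_numpy(), n_reps=2000, seed=3)
        assert a.p_monte_carlo == b.p_monte_carlo

    def test_too_few_reps_rejected(self, table2_counts):
        with pytest.raises(ParameterError):
            monte_carlo_chi2(table2_counts.to_numpy(), n_reps=10, seed=0)


class TestHWE:
    def test_published_control_counts(self):
        # closed-form oracle: p_H = 144/404; expected (25.66, 92.68, 83.66)
        res = hwe_test(32, 80, 90)
        p_h = 144 / 404
        expected = np.array([p_h**2, 2 * p_h * (1 - p_h), (1 - p_h) ** 2]) * 202
        chi2_oracle = (((np.array([32, 80, 90]) - expected) ** 2) / expected).sum()
        assert math.isclose(res.chi2, chi2_oracle, rel_tol=1e-12)
        assert round(res.chi2, 2) == 3.78
        assert 0.05 < res.p < 0.06
        assert math.isclose(res.allele_freq, p_h)

    def test_exact_proportions_give_zero(self):
        res = hwe_test(25, 50, 25)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_extreme_heterozygote_deficit(self):
        # expected (25, 50, 25): chi2 = 25 + 50 + 25 = 100
        res = hwe_test(50, 0, 50)
        assert math.isclose(res.chi2, 100.0)
        assert res.p < 1e-20

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            hwe_test(0, 0, 0)


class TestTabulate:
    def test_female_a02_stratum_counts_and_percentages(self, table2_subjects):
        t = tabulate(table2_subjects, sex="female", a02="yes")
        assert tuple(t.counts.loc["case"]) == (26, 146, 165)
        assert tuple(t.counts.loc["control"]) == (32, 80, 90)
        pct = t.percentages()
        assert tuple(pct.loc["case"]) == (7.7, 43.3, 49.0)
        assert tuple(pct.loc["control"]) == (15.8, 39.6, 44.6)

    def test_male_stratum_counts(self, table3_subjects):
        t = tabulate(table3_subjects, sex="male", a02="yes")
        assert tuple(t.counts.loc["case"]) == (18, 85, 75)
        assert tuple(t.counts.loc["control"]) == (21, 88, 85)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            tabulate([], sex="female")

    def test_unknown_carriage_excluded(self):
        subjects = [
            SubjectRecord("a", "case", "female", "RR", a02_carrier="unknown"),
            SubjectRecord("b", "case", "female", "RH", a02_carrier="yes"),
            SubjectRecord("c", "control", "female", "RR", a02_carrier="yes"),
        ]
        t = tabulate(subjects, a02="yes")
        assert t.counts.to_numpy().sum() == 2


class TestSubjectRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"status": "patient"},
            {"sex": "f"},
            {"lmp2": "RX"},
            {"a02_carrier": "maybe"},
            {"status": "control", "onset_age": 30.0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(subject_id="s", status="case", sex="female", lmp2="RR")
        with pytest.raises(ParameterError):
            SubjectRecord(**{**base, **kwargs})


class TestCohortHomogeneity:
    def test_identical_distributions_are_homogeneous(self, table2_subjects):
        t = tabulate(table2_subjects, sex="female", a02="yes")
        res = cohort_homogeneity(t, t)
        assert res.chi2 == 0.0 and res.p_asymptotic == 1.0

    def test_different_allele_frequencies_detected(self):
        def cohort(freq, seed):
            cfg = GenotypeSimConfig(n_subjects=1000, h_allele_freq=freq, seed=seed,
                                    baseline_case_logodds=5.0)  # nearly all cases
            return tabulate(list(simulate_population(cfg)))

        res = cohort_homogeneity(cohort(0.2, 1), cohort(0.5, 2))
        assert res.p_asymptotic < 0.001


class TestOnsetAge:
    def test_identical_groups_show_no_effect(self):
        ages = [30.0, 31.0, 29.0, 33.0]
        res, table = onset_age_compare({"HH": ages, "RH": ages, "RR": ages})
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert (table["mean"] == 30.75).all()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(30, 5, 30)
        b = rng.normal(40, 5, 30)  # 2 SD shift
        res, _ = onset_age_compare({"a": a, "b": b}, n_permutations=2000, seed=1)
        assert res.p_value < 0.01

    def test_degenerate_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            onset_age_compare({"a": [30.0], "b": [31.0, 32.0]})


class TestModelInterface:
    def test_fit_reproduces_published_panel(self, table2_subjects):
        model = CaseControlAssociation(table2_subjects, sex="female", a02="yes")
        res = model.fit(n_reps=2000, seed=5)
        by_name = {name: orr for name, orr, _ in res.contrasts}
        assert round(by_name["HH vs RR"].odds_ratio, 3) == 0.443
        assert round(res.overall.p_asymptotic, 3) == 0.013
        assert res.overall_mc.n_reps == 2000 and res.overall_mc.seed == 5
        text = res.summary()
        assert "0.443" in text and "HWE" in text

    def test_summary_roundtrips_to_dict(self, table2_counts):
        res = CaseControlAssociation.from_counts(table2_counts).fit()
        d = res.to_dict()
        assert d["counts"]["case"]["HH"] == 26
        assert round(d["contrasts"]["HH vs RR"]["odds_ratio"], 3) == 0.443
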