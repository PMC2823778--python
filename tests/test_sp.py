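"""Specific production: formula, bins, standardization, group comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lmp2ms import (
    DigestionSimConfig,
    DigestionStudy,
    assign_bin,
    compare_sp_by_genotype,
    compare_sp_pa28,
    compute_sp,
    levene_test,
    percent_decrease,
    simulate_digestion,
    sp_estimates,
    standardize_within_set,
)
from lmp2ms.exceptions import InsufficientDataError, ParameterError, UndefinedSPError
from lmp2ms.sp import BINS, EXCLUDED

from conftest import make_experiment


class TestComputeSP:
    def test_direct_formula(self):
        assert compute_sp(50.0, 200.0) == 250.0

    def test_zero_fragment(self):
        assert compute_sp(0.0, 200.0) == 0.0

    def test_undefined_without_consumption(self):
        with pytest.raises(UndefinedSPError):
            compute_sp(50.0, 0.0)

    def test_equals_scaled_yield_on_noiseless_generator(self):
        # SP = 1000 * yield exactly when noise and batch effects are absent
        cfg = DigestionSimConfig(noise_sd=0.0, batch_scale_sd=0.0,
                                 h_carrier_yield_ratio=1.0,
                                 pa28_epitope_yield_multiplier=1.0, seed=0)
        ests = sp_estimates(list(simulate_digestion(cfg)))
        for e in ests:
            expected = {"1-9": 0.30, "10-18": 0.25, "19-28": 0.20}[e.fragment_name]
            assert math.isclose(e.sp, 1000 * expected, rel_tol=1e-9)


class TestAssignBin:
    @pytest.mark.parametrize(
        "consumption, expected",
        [
            (0.10, "lt25"),
            (0.0, "lt25"),
            (0.2499, "lt25"),
            (0.25, "b25_35"),
            (0.349, "b25_35"),
            (0.35, "b35_50"),
            (0.4999, "b35_50"),
            (0.50, EXCLUDED),
            (0.99, EXCLUDED),
            (1.0, EXCLUDED),
        ],
    )
    def test_half_open_boundaries(self, consumption, expected):
        assert assign_bin(consumption) == expected

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ParameterError):
            assign_bin(bad)

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unit_interval(self, consumption):
        name = assign_bin(consumption)
        members = [b for b, (lo, hi) in BINS.items() if lo <= consumption < hi]
        assert (members == [name]) or (name == EXCLUDED and not members)


class TestStandardization:
    def _estimates(self, sps, set_id="s1"):
        exps = []
        for i, sp_val in enumerate(sps):
            exp = make_experiment(set_id=set_id, prep_id=f"p{i}",
                                  yields={"10-18": sp_val / 1000.0},
                                  times=(0.0, 30.0, 60.0, 120.0))
            exps.append(exp)
        return [e for e in sp_estimates(exps) if e.time == 30.0]

    def test_sample_sd_zscores(self):
        # sample-SD (ddof=1) convention: sd of {100,200,300} is 100
        out = standardize_within_set(self._estimates([100, 200, 300]))
        z = sorted(e.sp_standardized for e in out)
        assert z == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_passes_through_with_warning(self, caplog):
        out = standardize_within_set(self._estimates([100, 100, 100]))
        assert all(e.sp_standardized is None for e in out)
        assert "variance" in caplog.text

    def test_batch_factor_cancels_across_sets(self):
        # two sets identical except for a 3x detector factor
        cfg = dict(k1=0.01, times=(0.0, 30.0, 60.0, 120.0))
        exps = []
        for set_id, batch in (("sA", 1.0), ("sB", 3.0)):
            for i, y in enumerate((0.1, 0.2, 0.3)):
                exps.append(make_experiment(set_id=set_id, prep_id=f"{set_id}p{i}",
                                            batch=batch, yields={"10-18": y}, **cfg))
        out = standardize_within_set(sp_estimates(exps))
        za = sorted(e.sp_standardized for e in out if e.set_id == "sA")
        zb = sorted(e.sp_standardized for e in out if e.set_id == "sB")
        assert za == pytest.approx(zb, rel=1e-9)


class TestGenotypeComparison:
    def test_noiseless_decrease_matches_yield_ratio_in_every_bin(self):
        cfg = DigestionSimConfig(noise_sd=0.0, batch_scale_sd=0.0,
                                 h_carrier_yield_ratio=0.712, seed=0)
        ests = sp_estimates(list(simulate_digestion(cfg)))
        for bin_name in BINS:
            res = compare_sp_by_genotype(ests, bin_name, mode="h_carrier_t")
            assert res.percent_decrease == pytest.approx(28.8, abs=1e-9)
            assert res.p < 0.001

    def test_no_injected_effect_gives_identical_sp(self):
        cfg = DigestionSimConfig(noise_sd=0.0, batch_scale_sd=0.0,
                                 h_carrier_yield_ratio=1.0, seed=0)
        ests = [e for e in sp_estimates(list(simulate_digestion(cfg)))
                if e.fragment_name == "10-18" and e.pa28 and e.bin != EXCLUDED]
        sps = {round(e.sp, 6) for e in ests}
        assert len(sps) == 1  # identical across genotypes at matched consumption
        res = compare_sp_by_genotype(ests, "lt25", mode="h_carrier_t")
        assert res.percent_decrease == pytest.approx(0.0, abs=1e-9)

    def test_equal_means_with_noise_are_null(self):
        cfg = DigestionSimConfig(h_carrier_yield_ratio=1.0, noise_sd=0.15, seed=17)
        ests = sp_estimates(list(simulate_digestion(cfg)))
        res = compare_sp_by_genotype(ests, "lt25", mode="h_carrier_t")
        assert res.p > 0.05
        assert abs(res.percent_decrease) < 25

    def test_three_group_permutation_mode(self):
        cfg = DigestionSimConfig(noise_sd=0.1, seed=2)
        ests = sp_estimates(list(simulate_digestion(cfg)))
        res = compare_sp_by_genotype(ests, "lt25", mode="three_group_mc_anova",
                                     n_permutations=2000, seed=4)
        assert res.statistic_name == "F"
        assert set(res.groups) == {"RR", "RH", "HH"}
        assert 0.0 <= res.p <= 1.0

    def test_small_groups_rejected(self):
        cfg = DigestionSimConfig(n_preparations_per_genotype=(1, 0, 0), seed=0)
        ests = sp_estimates(list(simulate_digestion(cfg)))
        with pytest.raises(InsufficientDataError):
            compare_sp_by_genotype(ests, "lt25", mode="h_carrier_t")


class TestPA28Comparison:
    def test_complete_separation_six_per_group(self):
        res = compare_sp_pa28([10.0, 11, 12, 13, 14, 15], [1.0, 2, 3, 4, 5, 6])
        assert res.statistic_value == 0.0
        assert res.p == pytest.approx(2 / 924)
        assert round(res.p, 3) == 0.002

    def test_complete_separation_three_per_group(self):
        res = compare_sp_pa28([10.0, 11, 12], [1.0, 2, 3])
        assert res.p == pytest.approx(2 / 20)

    def test_balanced_ranks_are_null(self):
        res = compare_sp_pa28([1.0, 4.0], [2.0, 3.0])
        assert res.p == 1.0

    def test_exact_p_matches_scipy_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            ours = compare_sp_pa28(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_sp_pa28([], [1.0, 2.0])


class TestLevene:
    def test_identical_groups(self):
        res = levene_test([[1.0, 2, 3], [1.0, 2, 3]])
        assert res.statistic_value == 0.0 and res.p == 1.0

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 0.05, 20)
        b = rng.normal(0, 5.0, 20)
        res = levene_test([a, b])
        assert res.p < 0.01

    def test_degenerate_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            levene_test([[1.0], [2.0, 3.0]])


class TestDigestionStudy:
    def test_noiseless_panels_match_closed_form(self):
        cfg = DigestionSimConfig(noise_sd=0.0, batch_scale_sd=0.0, seed=0)
        res = DigestionStudy(list(simulate_digestion(cfg))).fit(seed=1)
        # K1 identical within condition -> F = 0, p = 1
        assert res.k1_anova.statistic == 0.0 and res.k1_anova.p_value == 1.0
        # fitted K1 ratio equals the PA28 multiplier by construction
        kin = res.kinetics
        ratio = (kin[kin.pa28].k1.mean() / kin[~kin.pa28].k1.mean())
        assert ratio == pytest.approx(3.0, rel=1e-9)
        for bin_name, panel in res.genotype_panels["pa28_present"].items():
            assert panel.percent_decrease == pytest.approx(28.8, abs=1e-9)
        # PA28 raises epitope SP: complete separation, exact U = 0
        epi = res.pa28_panels["10-18"]
        assert epi.statistic_value == 0.0 and epi.p < 0.05

    def test_summary_mentions_key_panels(self):
        cfg = DigestionSimConfig(seed=3)
        res = DigestionStudy(list(simulate_digestion(cfg))).fit(seed=3)
        text = res.summary()
        assert "K1 by genotype" in text and "PA28 effect" in text
        d = res.to_dict()
        assert "genotype_effect" in d and "k1_anova" in d
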