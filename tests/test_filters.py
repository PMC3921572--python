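"""Filter predicate semantics, composition, sweeps and Venn attribution."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from trioclean import (
    DEFAULT_TRIO,
    FilterConfig,
    SimulationParams,
    alt_allele_ratio,
    alt_ratio_pass,
    apply_filters,
    count_child_variants,
    count_mendelian_errors,
    depth_pass,
    exclusion_venn,
    filter_sweep,
    genotype_quality_pass,
    resolve_depth_threshold,
    simulate_trio_cohort,
)
from trioclean.filters import ALL_FILTERS, FILTER_AB, FILTER_DP, FILTER_GQ
from trioclean.model import HET, HOM_ALT, HOM_REF, MISSING

from conftest import TRIO, build_cohort, gc, preprocess

CFG = FilterConfig(adaptive_depth=False)


class TestAltAlleleRatio:
    @pytest.mark.parametrize("ad,expected", [
        ((10, 10), 0.5),
        ((0, 25), 1.0),
        ((16, 4), 0.2),   # the characteristic artifact peak
        ((0, 0), None),
        (None, None),
    ])
    def test_ratio(self, ad, expected):
        call = gc("het", ad=ad)
        assert alt_allele_ratio(call) == expected


class TestPredicateBoundaries:
    @pytest.mark.parametrize("dp,passes", [(14, False), (15, True), (2500, True)])
    def test_depth_strict_inequality(self, dp, passes):
        assert depth_pass(gc("het", dp=dp), min_dp=15) is passes

    def test_depth_absent_passes_unless_strict(self):
        assert depth_pass(gc("het"), min_dp=15)
        assert not depth_pass(gc("het"), min_dp=15, strict_missing=True)

    def test_optional_high_depth_cutoff(self):
        assert not depth_pass(gc("het", dp=2500), min_dp=15, max_dp=800)

    @pytest.mark.parametrize("gq,passes", [(19, False), (20, True), (99, True)])
    def test_genotype_quality_strict_inequality(self, gq, passes):
        assert genotype_quality_pass(gc("het", gq=gq), min_gq=20) is passes

    @pytest.mark.parametrize("gt,ad,passes", [
        # heterozygous window is the open interval (0.3, 0.7); bounds pass
        ("het", (16, 4), False),    # 0.20
        ("het", (71, 29), False),   # 0.29
        ("het", (7, 3), True),      # 0.30 boundary
        ("het", (1, 1), True),      # 0.50
        ("het", (3, 7), True),      # 0.70 boundary
        ("het", (29, 71), False),   # 0.71
        # hom_ref fails strictly above 0.15
        ("hom_ref", (17, 3), True),   # 0.15 boundary
        ("hom_ref", (4, 1), False),   # 0.20
        # hom_alt fails strictly below 0.85
        ("hom_alt", (3, 17), True),   # 0.85 boundary
        ("hom_alt", (4, 21), False),  # 0.84
        ("hom_alt", (0, 30), True),   # 1.0
    ])
    def test_allele_balance_windows(self, gt, ad, passes):
        assert alt_ratio_pass(gc(gt, ad=ad), CFG) is passes

    def test_undefined_ratio_and_missing_genotype_pass(self):
        assert alt_ratio_pass(gc("het"), CFG)
        assert alt_ratio_pass(gc("missing", ad=(16, 4)), CFG)
        strict = FilterConfig(strict_missing=True)
        assert not alt_ratio_pass(gc("het"), strict)


class TestAdaptiveDepth:
    @pytest.mark.parametrize("mean,expected", [
        (106, 15),   # high-coverage set: hard 15-read filter
        (50, 10),    # low-coverage: 20% of the mean
        (75, 15),    # boundary: 0.2*75 and the hard filter coincide
        (200, 15),
        (30, 6),
    ])
    def test_threshold_resolution(self, mean, expected):
        assert resolve_depth_threshold(mean, FilterConfig()) == expected

    def test_adaptive_off_always_hard(self):
        assert resolve_depth_threshold(30, FilterConfig(adaptive_depth=False)) == 15


def three_member_cohort():
    return build_cohort([
        # child fails all three filters, parents clean
        {"C": gc("het", dp=8, gq=12, ad=(16, 4)),
         "F": gc("het", dp=100, gq=99, ad=(50, 50)),
         "M": gc("hom_ref", dp=90, gq=99, ad=(90, 0))},
        # everyone clean
        {"C": gc("het", dp=100, gq=99, ad=(48, 52)),
         "F": gc("hom_ref", dp=80, gq=99, ad=(80, 0)),
         "M": gc("hom_ref", dp=85, gq=99, ad=(85, 0))},
        # both parents fail, child remains: still counted for the child
        {"C": gc("het", dp=95, gq=99, ad=(47, 48)),
         "F": gc("het", dp=5, gq=10, ad=(4, 1)),
         "M": gc("het", dp=6, gq=8, ad=(5, 1))},
        # only a failing parent carries the variant: site dropped
        {"C": gc("hom_ref", dp=90, gq=99, ad=(90, 0)),
         "F": gc("het", dp=4, gq=9, ad=(3, 1)),
         "M": gc("hom_ref", dp=80, gq=99, ad=(80, 0))},
    ])


class TestApplyFilters:
    def test_attribution_and_retention(self):
        cohort = three_member_cohort()
        filtered, attribution = apply_filters(cohort, TRIO, CFG)
        assert attribution.failed_filters(0, 0) == frozenset({"DP", "GQ", "AB"})
        assert attribution.failed_filters(1, 0) == frozenset()
        # removed genotypes become missing, never another called genotype
        assert filtered.gt[0, 0] == MISSING
        assert filtered.call(0, "F").gt == HET

    def test_child_counting_convention(self):
        cohort = three_member_cohort()
        filtered, _ = apply_filters(cohort, TRIO, CFG)
        # site 3 (parents removed, child het remains) still counts for the
        # child; site 1's child was removed (not counted) but the father's
        # variant keeps the site; site 4's only variant was removed -> dropped
        assert count_child_variants(filtered, TRIO) == 2
        assert filtered.n_sites == 3

    def test_idempotence(self):
        cohort = three_member_cohort()
        once, _ = apply_filters(cohort, TRIO, CFG)
        twice, _ = apply_filters(once, TRIO, CFG)
        assert twice.equals(once)

    def test_idempotence_on_simulated_cohort(self, default_sim_filtered):
        _, filtered, _ = default_sim_filtered
        again, _ = apply_filters(filtered, DEFAULT_TRIO)
        assert again.equals(filtered)

    def test_order_independence_exact(self):
        """Sequentially applying the predicates in any order equals the
        one-shot composition — each predicate is evaluated on original calls."""
        cohort, _ = simulate_trio_cohort(SimulationParams(seed=77, n_sites=300))
        pre = preprocess(cohort)
        reference, _ = apply_filters(pre, DEFAULT_TRIO, CFG)

        def predicate_fail(call, name):
            if name == FILTER_DP:
                return not depth_pass(call, CFG.min_dp, CFG.max_dp)
            if name == FILTER_GQ:
                return not genotype_quality_pass(call, CFG.min_gq)
            return not alt_ratio_pass(call, CFG)

        for order in itertools.permutations(ALL_FILTERS):
            current = pre.copy()
            for name in order:
                for i in range(current.n_sites):
                    for j in range(len(current.samples)):
                        call = current.call(i, j)
                        if call.is_called and predicate_fail(call, name):
                            current.gt[i, j] = MISSING
            ic, ifa, imo = current.trio_indices(DEFAULT_TRIO)
            g = current.gt[:, [ic, ifa, imo]]
            keep = ((g == HET) | (g == HOM_ALT)).any(axis=1)
            current = current.take_sites(keep)
            assert current.sites == reference.sites
            assert np.array_equal(current.gt, reference.gt)

    def test_never_rewrites_a_called_genotype(self, default_sim, default_sim_filtered):
        _, cohort, _ = default_sim
        pre, filtered, _ = default_sim_filtered
        pre_index = {k: i for i, k in enumerate(pre.sites)}
        rows = [pre_index[k] for k in filtered.sites]
        before = pre.gt[rows]
        after = filtered.gt
        changed = before != after
        assert (after[changed] == MISSING).all()


class TestVenn:
    def test_toy_attribution_regions(self):
        cohort = build_cohort([
            {"C": gc("het", dp=5, gq=99, ad=(3, 2))},       # DP only
            {"C": gc("het", dp=5, gq=10, ad=(3, 2))},       # DP and GQ
        ])
        _, attribution = apply_filters(cohort, TRIO, CFG)
        regions = exclusion_venn(attribution)
        assert regions[frozenset({"DP"})] == 1
        assert regions[frozenset({"DP", "GQ"})] == 1
        assert sum(regions.values()) == 2

    def test_empty_attribution_all_zeros(self):
        cohort = build_cohort([
            {"C": gc("het", dp=100, gq=99, ad=(50, 50))},
        ])
        _, attribution = apply_filters(cohort, TRIO, CFG)
        regions = exclusion_venn(attribution)
        assert set(map(len, regions)) == {1, 2, 3}
        assert all(v == 0 for v in regions.values())

    def test_region_counts_sum_to_total_excluded(self, default_sim_filtered):
        _, _, attribution = default_sim_filtered
        regions = exclusion_venn(attribution)
        assert len(regions) == 7
        assert sum(regions.values()) == attribution.n_excluded()


class TestSweep:
    def test_zero_threshold_is_unfiltered(self, default_sim_filtered):
        pre, _, _ = default_sim_filtered
        rows = filter_sweep(pre, DEFAULT_TRIO, "DP", [0])
        assert rows[0]["variants_remaining"] == count_child_variants(pre, DEFAULT_TRIO)
        assert rows[0]["mendelian_errors_remaining"] == \
            count_mendelian_errors(pre, DEFAULT_TRIO).n_errors

    @pytest.mark.parametrize("axis,grid", [
        ("DP", [0, 5, 10, 15, 20, 30]),
        ("GQ", [0, 10, 20, 40, 80]),
    ])
    def test_monotone_non_increasing(self, default_sim_filtered, axis, grid):
        pre, _, _ = default_sim_filtered
        rows = filter_sweep(pre, DEFAULT_TRIO, axis, grid)
        variants = [r["variants_remaining"] for r in rows]
        errors = [r["mendelian_errors_remaining"] for r in rows]
        assert variants == sorted(variants, reverse=True) or all(
            a >= b for a, b in zip(variants, variants[1:]))
        assert all(a >= b for a, b in zip(errors, errors[1:]))

    def test_unsorted_grid_rejected(self, default_sim_filtered):
        pre, _, _ = default_sim_filtered
        with pytest.raises(ValueError):
            filter_sweep(pre, DEFAULT_TRIO, "DP", [15, 10])


class TestConfigValidation:
    def test_bad_windows_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(het_ab_low=0.8, het_ab_high=0.7)
        with pytest.raises(ValueError):
            FilterConfig(homref_ab_max=0.9, homalt_ab_min=0.85)
        with pytest.raises(ValueError):
            FilterConfig(min_gq=120)
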