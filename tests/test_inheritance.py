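"""De novo, recessive-homozygous and compound-het candidate identification."""

from __future__ import annotations

import numpy as np
import pytest

from trioclean import (
    DEFAULT_TRIO,
    SimulationParams,
    VariantKey,
    apply_filters,
    classify_trio_genotype,
    find_compound_heterozygous,
    find_de_novo,
    find_recessive_homozygous,
    intersect_across_sources,
    read_annotations,
    simulate_trio_cohort,
)
from trioclean.inheritance import AnnotationRecord, CandidateSet, DE_NOVO
from trioclean.mendel import MENDELIAN_ERROR
from trioclean.simulate import synthesize_annotations, write_annotation_tsv

from conftest import TRIO, build_cohort, gc, preprocess


def ann(key, gene="GENE1", effect="nonsynonymous", af=0.0):
    return AnnotationRecord(key=key, gene=gene, effect=effect, af=af)


def keyed(pos):
    return VariantKey("chr1", pos, "A", "G")


def cohort_of(rows):
    return build_cohort(rows, samples=("C", "F", "M"))


class TestDeNovo:
    def test_classic_configuration_is_a_candidate(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("het"), "F": gc("hom_ref"), "M": gc("hom_ref")})])
        out = find_de_novo(cohort, TRIO, {k: ann(k)})
        assert [v for v, _ in out.variants] == [k]

    def test_missing_parent_disqualifies(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("het"), "F": gc("hom_ref"), "M": gc("missing")})])
        assert len(find_de_novo(cohort, TRIO, {k: ann(k)})) == 0

    @pytest.mark.parametrize("effect,expected", [
        ("nonsynonymous", 1), ("splicing", 1), ("insertion", 1), ("deletion", 1),
        ("start_codon_change", 1), ("stop_codon_change", 1), ("other", 0),
    ])
    def test_effect_class_membership(self, effect, expected):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("het"), "F": gc("hom_ref"), "M": gc("hom_ref")})])
        assert len(find_de_novo(cohort, TRIO, {k: ann(k, effect=effect)})) == expected

    def test_unannotated_site_not_a_candidate(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("het"), "F": gc("hom_ref"), "M": gc("hom_ref")})])
        assert len(find_de_novo(cohort, TRIO, {})) == 0


class TestRecessiveHomozygous:
    def test_rare_candidate(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("hom_alt"), "F": gc("het"), "M": gc("het")})])
        out = find_recessive_homozygous(cohort, TRIO, {k: ann(k, af=0.001)})
        assert len(out) == 1

    def test_common_variant_excluded(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("hom_alt"), "F": gc("het"), "M": gc("het")})])
        assert len(find_recessive_homozygous(cohort, TRIO, {k: ann(k, af=0.02)})) == 0

    def test_non_het_parent_excluded(self):
        k = keyed(100)
        cohort = cohort_of([(k, {"C": gc("hom_alt"), "F": gc("hom_ref"), "M": gc("het")})])
        assert len(find_recessive_homozygous(cohort, TRIO, {k: ann(k, af=0.0)})) == 0

    def test_candidates_shrink_as_af_threshold_tightens(self):
        keys = [keyed(100 + i) for i in range(6)]
        afs = [0.0, 0.002, 0.005, 0.009, 0.02, 0.04]
        cohort = cohort_of([
            (k, {"C": gc("hom_alt"), "F": gc("het"), "M": gc("het")}) for k in keys
        ])
        annotations = {k: ann(k, af=a) for k, a in zip(keys, afs)}
        sizes = [
            len(find_recessive_homozygous(cohort, TRIO, annotations, af_max=t))
            for t in (0.05, 0.01, 0.005, 0.001)
        ]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == 6 and sizes[-1] == 1


class TestCompoundHet:
    def two_variant_gene(self, father_gts, mother_gts, afs):
        k1, k2 = keyed(100), keyed(200)
        cohort = cohort_of([
            (k1, {"C": gc("het"), "F": gc(father_gts[0]), "M": gc(mother_gts[0])}),
            (k2, {"C": gc("het"), "F": gc(father_gts[1]), "M": gc(mother_gts[1])}),
        ])
        annotations = {k1: ann(k1, af=afs[0]), k2: ann(k2, af=afs[1])}
        return cohort, annotations, (k1, k2)

    def test_classic_trans_configuration(self):
        cohort, annotations, (k1, k2) = self.two_variant_gene(
            ("het", "hom_ref"), ("hom_ref", "het"), (0.004, 0.03))
        out = find_compound_heterozygous(cohort, TRIO, annotations)
        assert out.pairs == [("GENE1", k1, k2)]
        assert {v for v, _ in out.variants} == {k1, k2}

    def test_parent_carrying_both_excluded(self):
        cohort, annotations, _ = self.two_variant_gene(
            ("het", "het"), ("hom_ref", "hom_ref"), (0.004, 0.004))
        assert len(find_compound_heterozygous(cohort, TRIO, annotations)) == 0

    def test_neither_variant_rare_excluded(self):
        cohort, annotations, _ = self.two_variant_gene(
            ("het", "hom_ref"), ("hom_ref", "het"), (0.04, 0.03))
        assert len(find_compound_heterozygous(cohort, TRIO, annotations)) == 0

    def test_loose_variant_above_five_percent_excluded(self):
        cohort, annotations, _ = self.two_variant_gene(
            ("het", "hom_ref"), ("hom_ref", "het"), (0.004, 0.08))
        assert len(find_compound_heterozygous(cohort, TRIO, annotations)) == 0

    def test_missing_parent_genotype_disqualifies_pair(self):
        cohort, annotations, _ = self.two_variant_gene(
            ("het", "missing"), ("hom_ref", "het"), (0.004, 0.004))
        assert len(find_compound_heterozygous(cohort, TRIO, annotations)) == 0

    def test_different_genes_never_pair(self):
        k1, k2 = keyed(100), keyed(200)
        cohort = cohort_of([
            (k1, {"C": gc("het"), "F": gc("het"), "M": gc("hom_ref")}),
            (k2, {"C": gc("het"), "F": gc("hom_ref"), "M": gc("het")}),
        ])
        annotations = {k1: ann(k1, gene="G1"), k2: ann(k2, gene="G2")}
        assert len(find_compound_heterozygous(cohort, TRIO, annotations)) == 0


class TestAnnotationTable:
    def test_round_trip_and_max_af(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect\taf_1kg\taf_esp\taf_internal\n"
            "chr1\t100\tA\tG\tGENE1\tnonsynonymous\t0.001\t0.02\t\n"
            "chr1\t200\tC\tT\tGENE2\tother\t\t\t\n"
        )
        table = read_annotations(path)
        rec = table[VariantKey("chr1", 100, "A", "G")]
        assert rec.af == pytest.approx(0.02)  # max over provided sources
        assert table[VariantKey("chr1", 200, "C", "T")].af == 0.0  # novel
        with pytest.raises(ValueError, match="lacks columns"):
            bad = tmp_path / "bad.tsv"
            bad.write_text("chrom\tpos\n1\t2\n")
            read_annotations(bad)

    def test_synthesized_annotations_round_trip(self, tmp_path):
        _, truth = simulate_trio_cohort(SimulationParams(seed=4, n_sites=500))
        annotations = synthesize_annotations(truth, seed=4)
        path = tmp_path / "synth.tsv"
        write_annotation_tsv(annotations, path)
        back = read_annotations(path)
        assert set(back) == set(annotations)
        for k in truth.de_novo_sites:
            assert back[k].effect == "nonsynonymous"
            assert back[k].af == 0.0


class TestIntersection:
    def three_identical_sets(self):
        k = keyed(100)
        cs = CandidateSet(model=DE_NOVO, variants=[(k, "GENE1")])
        return {
            "blood": CandidateSet(model=DE_NOVO, source_label="blood",
                                  variants=list(cs.variants)),
            "buccal": CandidateSet(model=DE_NOVO, source_label="buccal",
                                   variants=list(cs.variants)),
            "saliva": CandidateSet(model=DE_NOVO, source_label="saliva",
                                   variants=list(cs.variants)),
        }

    def test_identical_sets_all_common(self):
        inter = intersect_across_sources(self.three_identical_sets())
        assert inter.common_to_all == 1
        assert all(v == 0 for v in inter.unique_to_one.values())

    def test_candidate_in_one_source_counted_unique(self):
        sets = self.three_identical_sets()
        extra = keyed(500)
        sets["blood"].variants.append((extra, "GENE9"))
        inter = intersect_across_sources(sets)
        assert inter.unique_to_one["blood"] == 1
        assert inter.common_to_all == 1
        assert inter.called["blood"] == 2

    def test_mixed_models_rejected(self):
        sets = self.three_identical_sets()
        sets["saliva"].model = "recessive_homozygous"
        with pytest.raises(ValueError):
            intersect_across_sources(sets)


class TestCrossModuleConsistency:
    def test_every_de_novo_candidate_is_a_mendelian_error(self, default_sim):
        _, cohort, truth = default_sim
        pre = preprocess(cohort)
        filtered, _ = apply_filters(pre, DEFAULT_TRIO)
        annotations = synthesize_annotations(truth, seed=1)
        out = find_de_novo(filtered, DEFAULT_TRIO, annotations)
        index = {k: i for i, k in enumerate(filtered.sites)}
        for key, _gene in out.variants:
            i = index[key]
            verdict = classify_trio_genotype(
                filtered.call(i, "CHILD"), filtered.call(i, "FATHER"),
                filtered.call(i, "MOTHER"))
            assert verdict.status == MENDELIAN_ERROR

    def test_filtering_reduces_false_de_novo_candidates(self, default_sim):
        _, cohort, truth = default_sim
        pre = preprocess(cohort)
        filtered, _ = apply_filters(pre, DEFAULT_TRIO)
        annotations = synthesize_annotations(truth, seed=1)
        dn_truth = set(truth.de_novo_sites)
        before = {k for k, _ in find_de_novo(pre, DEFAULT_TRIO, annotations).variants}
        after = {k for k, _ in find_de_novo(filtered, DEFAULT_TRIO, annotations).variants}
        assert len(after - dn_truth) < len(before - dn_truth)
        # injected de novos carry true-call quality metrics and must survive
        assert dn_truth <= after
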