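"""Candidate causative variant identification under three inheritance models.

Runs on the *filtered* trio cohort joined against an external annotation /
allele-frequency table (the annotation is consumed, never computed):

* de novo — child heterozygous, both parents called homozygous reference;
* recessive homozygous — child homozygous alternate, both parents
  heterozygous, population allele frequency below 1%;
* compound heterozygous — at least two child-het variants in one gene with
  no single parent carrying both, one variant below 1% frequency and the
  other at most 5%.

All models are restricted to amino-acid-altering variants (nonsynonymous,
splicing, insertions, deletions, start/stop codon changes).  The effective
allele frequency of a variant is the maximum over the provided population
columns; a variant absent from the table is treated as novel (af = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import HET, HOM_ALT, HOM_REF, MISSING, CohortTable, Trio, VariantKey

DE_NOVO = "de_novo"
RECESSIVE_HOM = "recessive_homozygous"
COMPOUND_HET = "compound_heterozygous"

AMINO_ACID_ALTERING = frozenset({
    "nonsynonymous", "splicing", "insertion", "deletion",
    "start_codon_change", "stop_codon_change",
})


@dataclass(frozen=True)
class AnnotationRecord:
    key: VariantKey
    gene: str
    effect: str
    af: float  # effective population AF: max over sources, 0 if novel

    @property
    def is_amino_acid_altering(self) -> bool:
        return self.effect in AMINO_ACID_ALTERING


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Load a TSV annotation/AF table keyed on (chrom, pos, ref, alt).

    Required columns: chrom, pos, ref, alt, gene, effect; any column whose
    name starts with ``af_`` is treated as a population allele-frequency
    source, and the record's effective af is their maximum (missing values
    ignored; all missing -> 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        afs = [getattr(row, c) for c in af_cols]
        afs = [float(a) for a in afs if pd.notna(a)]
        out[key] = AnnotationRecord(
            key=key,
            gene=str(row.gene),
            effect=str(row.effect),
            af=max(afs) if afs else 0.0,
        )
    return out


@dataclass
class CandidateSet:
    """Candidates under one inheritance model for one cohort/source.

    ``variants`` lists (VariantKey, gene); for the compound-het model,
    ``pairs`` additionally lists (gene, key1, key2) for every qualifying
    pair, and variants in qualifying pairs are all listed.
    """

    model: str
    source_label: str = ""
    variants: list[tuple[VariantKey, str]] = field(default_factory=list)
    pairs: list[tuple[str, VariantKey, VariantKey]] = field(default_factory=list)

    @property
    def keys(self) -> set:
        if self.model == COMPOUND_HET:
            return {(g, k1, k2) for g, k1, k2 in self.pairs}
        return {k for k, _ in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


def _annotated_rows(cohort: CohortTable,
                    annotations: dict[VariantKey, AnnotationRecord]):
    for i, key in enumerate(cohort.sites):
        ann = annotations.get(key)
        if ann is not None and ann.is_amino_acid_altering:
            yield i, key, ann


def find_de_novo(cohort: CohortTable, trio: Trio,
                 annotations: dict[VariantKey, AnnotationRecord]) -> CandidateSet:
    """Child het with both parents called hom_ref, amino-acid-altering."""
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt
    out = CandidateSet(model=DE_NOVO, source_label=cohort.source_label)
    for i, key, ann in _annotated_rows(cohort, annotations):
        if g[i, ic] == HET and g[i, ifa] == HOM_REF and g[i, imo] == HOM_REF:
            out.variants.append((key, ann.gene))
    return out


def find_recessive_homozygous(cohort: CohortTable, trio: Trio,
                              annotations: dict[VariantKey, AnnotationRecord],
                              af_max: float = 0.01) -> CandidateSet:
    """Child hom_alt with both parents het and af below ``af_max``."""
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt
    out = CandidateSet(model=RECESSIVE_HOM, source_label=cohort.source_label)
    for i, key, ann in _annotated_rows(cohort, annotations):
        if (g[i, ic] == HOM_ALT and g[i, ifa] == HET and g[i, imo] == HET
                and ann.af < af_max):
            out.variants.append((key, ann.gene))
    return out


def find_compound_heterozygous(cohort: CohortTable, trio: Trio,
                               annotations: dict[VariantKey, AnnotationRecord],
                               af_loose: float = 0.05,
                               af_strict: float = 0.01) -> CandidateSet:
    """Gene-wise child-het pairs not jointly carried by either parent.

    A pair (v1, v2) qualifies when both are child-het and amino-acid-
    altering, no single parent has a called genotype with an alternate
    allele at both (a missing parental genotype at either site disqualifies
    the pair, conservatively), min(af) < ``af_strict`` and
    max(af) <= ``af_loose``.  Phase is never consulted — only the trio
    configuration constrains cis/trans.
    """
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt
    by_gene: dict[str, list[tuple[int, VariantKey, AnnotationRecord]]] = {}
    for i, key, ann in _annotated_rows(cohort, annotations):
        if g[i, ic] == HET:
            by_gene.setdefault(ann.gene, []).append((i, key, ann))

    def carries_alt(row: int, col: int) -> bool:
        return g[row, col] in (HET, HOM_ALT)

    out = CandidateSet(model=COMPOUND_HET, source_label=cohort.source_label)
    kept: set[VariantKey] = set()
    for gene, entries in by_gene.items():
        for (i1, k1, a1), (i2, k2, a2) in itertools.combinations(entries, 2):
            if g[i1, ifa] == MISSING or g[i2, ifa] == MISSING:
                continue
            if g[i1, imo] == MISSING or g[i2, imo] == MISSING:
                continue
            if carries_alt(i1, ifa) and carries_alt(i2, ifa):
                continue
            if carries_alt(i1, imo) and carries_alt(i2, imo):
                continue
            af_lo, af_hi = sorted((a1.af, a2.af))
            if af_lo < af_strict and af_hi <= af_loose:
                out.pairs.append((gene, k1, k2))
                for k in (k1, k2):
                    if k not in kept:
                        kept.add(k)
                        out.variants.append((k, gene))
    return out


@dataclass
class ModelIntersection:
    model: str
    called: dict[str, int]          # per-source candidate counts
    unique_to_one: dict[str, int]   # per-source count present in that source only
    common_to_all: int


def intersect_across_sources(candidate_sets: dict[str, CandidateSet]) -> ModelIntersection:
    """Cross-source attribution of one model's candidates.

    Candidates are matched on VariantKey (de novo / recessive) or on
    (gene, variant pair) for the compound-het model.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need candidate sets from at least two sources")
    models = {cs.model for cs in candidate_sets.values()}
    if len(models) != 1:
        raise ValueError(f"mixed models in intersection: {models}")
    model = models.pop()

    keys = {src: cs.keys for src, cs in candidate_sets.items()}
    all_keys = set().union(*keys.values())
    common = set.intersection(*keys.values())
    unique = {
        src: sum(
            1 for k in keys[src]
            if all(k not in keys[other] for other in keys if other != src)
        )
        for src in keys
    }
    return ModelIntersection(
        model=model,
        called={src: len(k) for src, k in keys.items()},
        unique_to_one=unique,
        common_to_all=len(common),
    )


def candidate_report(candidate_sets: list[CandidateSet],
                     annotations: dict[VariantKey, AnnotationRecord]) -> pd.DataFrame:
    """Per-variant candidate rows (model, gene, position, af, source)."""
    records = []
    for cs in candidate_sets:
        for key, gene in cs.variants:
            ann = annotations.get(key)
            records.append({
                "model": cs.model,
                "source": cs.source_label,
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": gene,
                "effect": ann.effect if ann else "",
                "af": ann.af if ann else 0.0,
            })
    return pd.DataFrame.from_records(
        records,
        columns=["model", "source", "chrom", "pos", "ref", "alt", "gene", "effect", "af"],
    )
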