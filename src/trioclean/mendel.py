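"""Mendelian-consistency classification of trio genotypes.

A Mendelian error (ME) is a child genotype that cannot arise by drawing one
allele from each parent at a biallelic site.  With one parental genotype
missing, an error can still be *inferred* when the child and the called
parent are opposite homozygotes (hom_ref vs hom_alt): no missing parent
could rescue that configuration.  A heterozygous child with only one called
parent is never evaluable, and neither is a site where the child or both
parents are uncalled.

In unfiltered short-read trio data, MEs are overwhelmingly sequencing
artifacts rather than true de novo mutations, which is what makes the ME
count a usable proxy for the artifact burden.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortTable,
    GenotypeCall,
    Trio,
)

# verdict status codes
CONSISTENT = 0
MENDELIAN_ERROR = 1
INFERRED_ERROR = 2
NOT_EVALUABLE = 3

STATUS_NAMES = {
    CONSISTENT: "consistent",
    MENDELIAN_ERROR: "mendelian_error",
    INFERRED_ERROR: "inferred_error",
    NOT_EVALUABLE: "not_evaluable",
}


@dataclass(frozen=True)
class MendelVerdict:
    status: int
    reason: str

    @property
    def status_name(self) -> str:
        return STATUS_NAMES[self.status]

    @property
    def is_error(self) -> bool:
        return self.status in (MENDELIAN_ERROR, INFERRED_ERROR)


#: alleles carried by each called genotype category
_ALLELES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def consistent_child_genotypes(father_gt: int, mother_gt: int) -> set[int]:
    """Child genotype categories obtainable by one allele from each parent."""
    if father_gt == MISSING or mother_gt == MISSING:
        raise ValueError("both parental genotypes must be called; "
                         "route missing-parent cases through classify_trio_genotype")
    out = set()
    for a in _ALLELES[father_gt]:
        for b in _ALLELES[mother_gt]:
            out.add(a + b)  # allele-count sum is the category code
    return out


def _classify_codes(child: int, father: int, mother: int) -> MendelVerdict:
    if child == MISSING:
        return MendelVerdict(NOT_EVALUABLE, "child_missing")
    n_parent_missing = (father == MISSING) + (mother == MISSING)
    if n_parent_missing == 2:
        return MendelVerdict(NOT_EVALUABLE, "both_parents_missing")
    if n_parent_missing == 1:
        called = father if father != MISSING else mother
        if child == HET:
            return MendelVerdict(NOT_EVALUABLE, "het_child_one_parent")
        if {child, called} == {HOM_REF, HOM_ALT}:
            return MendelVerdict(INFERRED_ERROR, "opposite_homozygotes")
        return MendelVerdict(CONSISTENT, "compatible_one_parent")
    if child in consistent_child_genotypes(father, mother):
        return MendelVerdict(CONSISTENT, "transmissible")
    return MendelVerdict(MENDELIAN_ERROR, "untransmissible")


# lookup over codes -1..2 (offset by 1) for the vectorised path
_STATUS_LUT = np.empty((4, 4, 4), dtype=np.int8)
for _c, _f, _m in itertools.product((MISSING, HOM_REF, HET, HOM_ALT), repeat=3):
    _STATUS_LUT[_c + 1, _f + 1, _m + 1] = _classify_codes(_c, _f, _m).status


def classify_trio_genotype(child: GenotypeCall, father: GenotypeCall,
                           mother: GenotypeCall) -> MendelVerdict:
    """Mendelian verdict for one trio genotype.

    Symmetric in father/mother; only the genotype categories matter
    (quality fields are the filters' business, not the classifier's).
    """
    return _classify_codes(child.gt, father.gt, mother.gt)


def classify_cohort(cohort: CohortTable, trio: Trio) -> np.ndarray:
    """Per-site verdict status codes for the trio, vectorised."""
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt
    return _STATUS_LUT[g[:, ic] + 1, g[:, ifa] + 1, g[:, imo] + 1]


@dataclass
class MendelSummary:
    """ME counts for one trio over one cohort.

    ``error_rate`` is n_errors over the child's called variants (the child
    counting convention: a site whose parental genotypes were filtered away
    still counts for the child as long as the child's call remains).
    """

    n_sites_evaluated: int
    n_errors: int
    n_inferred: int
    n_not_evaluable: int
    n_child_variants: int
    rate_defined: bool = True

    @property
    def error_rate(self) -> float:
        if not self.rate_defined or self.n_child_variants == 0:
            return 0.0
        return self.n_errors / self.n_child_variants

    @property
    def error_rate_percent(self) -> float:
        return 100.0 * self.error_rate


def count_mendelian_errors(cohort: CohortTable, trio: Trio) -> MendelSummary:
    """Classify every site for the trio and summarise the error burden.

    Expects a cohort already autosome-restricted and informative-site
    selected.  ``n_errors`` counts plain and inferred errors together (one
    number, as reported in practice).
    """
    status = classify_cohort(cohort, trio)
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt[:, [ic, ifa, imo]]
    child_called = g[:, 0] != MISSING
    any_nonref = ((g == HET) | (g == HOM_ALT)).any(axis=1)
    n_child = int((child_called & any_nonref).sum())
    n_me = int((status == MENDELIAN_ERROR).sum())
    n_inf = int((status == INFERRED_ERROR).sum())
    return MendelSummary(
        n_sites_evaluated=len(status),
        n_errors=n_me + n_inf,
        n_inferred=n_inf,
        n_not_evaluable=int((status == NOT_EVALUABLE).sum()),
        n_child_variants=n_child,
        rate_defined=n_child > 0,
    )


def expected_single_chromosome_sites(n_sites: float, depth: int) -> float:
    """Expected number of sites at which every read samples one homolog.

    Computed as ``n_sites * (1/2)**depth``.  At depth 10 over 5e7 sites this
    is ~5e4 and at depth 15 ~1.5e3, which is why a low-depth cutoff near 15
    reads removes most single-homolog sampling artifacts.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    return n_sites * 0.5 ** depth


# ---------------------------------------------------------------------------
# upload QC: ME abundance and sex verification


@dataclass
class TrioQC:
    trio: Trio
    error_rate: float
    abundant_errors: bool


@dataclass
class SampleSexQC:
    sample: str
    reported_sex: str
    x_het_fraction: float | None
    inferred_sex: str  # male-like / female-like / inconclusive / not_performed
    mismatch: bool


@dataclass
class QCReport:
    trios: list[TrioQC] = field(default_factory=list)
    sexes: list[SampleSexQC] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(t.abundant_errors for t in self.trios) and not any(
            s.mismatch for s in self.sexes
        )


def qc_cohort(cohort: CohortTable, trios: list[Trio], sexes: dict[str, str],
              me_abundance_threshold: float = 0.10,
              male_max_het: float = 0.05, female_min_het: float = 0.20) -> QCReport:
    """Upload QC: flag trios with an abundance of MEs and sex mismatches.

    Runs on the cohort *before* autosome restriction (the sex check needs X
    sites).  The ME rate per trio is computed on that trio's autosomal
    informative sites; a sample is male-like when its X heterozygosity
    fraction is below ``male_max_het``, female-like above ``female_min_het``,
    inconclusive between.  All cutoffs are configurable defaults.
    """
    from .io import _normalize_chrom, restrict_to_autosomes, select_informative_sites

    report = QCReport()
    autosomal = restrict_to_autosomes(cohort)
    for trio in trios:
        summary = count_mendelian_errors(select_informative_sites(autosomal, trio), trio)
        report.trios.append(TrioQC(
            trio=trio,
            error_rate=summary.error_rate,
            abundant_errors=summary.error_rate > me_abundance_threshold,
        ))

    x_rows = [i for i, k in enumerate(cohort.sites) if _normalize_chrom(k.chrom) == "X"]
    for sample in cohort.samples:
        reported = sexes.get(sample, "unknown")
        if not x_rows:
            report.sexes.append(SampleSexQC(sample, reported, None, "not_performed", False))
            continue
        j = cohort.sample_index(sample)
        g = cohort.gt[x_rows, j]
        called = g != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            report.sexes.append(SampleSexQC(sample, reported, None, "not_performed", False))
            continue
        het_frac = float((g == HET).sum() / n_called)
        if het_frac < male_max_het:
            inferred = "male-like"
        elif het_frac > female_min_het:
            inferred = "female-like"
        else:
            inferred = "inconclusive"
        mismatch = (reported == "male" and inferred == "female-like") or (
            reported == "female" and inferred == "male-like"
        )
        report.sexes.append(SampleSexQC(sample, reported, het_frac, inferred, mismatch))
    return report
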