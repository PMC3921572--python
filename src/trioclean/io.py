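"""VCF / FAM input-output and site-level preprocessing.

Reading and writing go through :mod:`pysam`; multi-allelic records are
decomposed here into one biallelic record per alternate allele, because the
whole downstream analysis (Mendelian classification, genotype filters,
concordance) is defined on biallelic sites.

Decomposition rule for alternate allele ``k``: a genotype is het if exactly
one allele index equals ``k``, hom_alt if both do, hom_ref if neither does
and no allele is missing; ``ad_ref`` is the AD entry of the reference
allele, ``ad_alt`` the AD entry of allele ``k``.  Half-calls (``./1``) are
treated as missing, and phase separators are ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .model import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortTable,
    Trio,
    VariantKey,
)

SEX_CHROMS = {"X", "Y"}
#: FORMAT key used to tag genotypes removed by the quality filters
FILTER_REASON_KEY = "FR"


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending position when known."""


def _normalize_chrom(chrom: str) -> str:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper()


def _decompose_gt(alleles: tuple[int | None, ...], k: int) -> int:
    """Genotype category of one sample for alternate allele index ``k``."""
    if not alleles or any(a is None for a in alleles):
        return MISSING
    hits = sum(1 for a in alleles if a == k)
    if hits == 0:
        return HOM_REF
    if hits == len(alleles) and len(alleles) > 1:
        return HOM_ALT
    if len(alleles) == 1:  # haploid call: treat single alt allele as hom_alt
        return HOM_ALT
    return HET


def read_vcf(path: str | Path, source_label: str = "") -> CohortTable:
    """Read a multi-sample VCF into a :class:`CohortTable`.

    Multi-allelic records are split into one biallelic record per alternate
    allele; absent FORMAT subfields stay absent (they are not coerced to 0).
    When DP is absent but AD present, DP is reconstructed as
    ``ad_ref + ad_alt``.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} contains no samples")

    sites: list[VariantKey] = []
    rows_gt: list[list[int]] = []
    rows_dp: list[list[int]] = []
    rows_gq: list[list[int]] = []
    rows_adr: list[list[int]] = []
    rows_ada: list[list[int]] = []

    for rec in vf:
        alts = rec.alts or ()
        for k, alt in enumerate(alts, start=1):
            if alt is None or alt in ("*", "<NON_REF>") or alt.startswith("<"):
                continue
            try:
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt).validate()
            except ValueError as exc:
                raise VcfParseError(f"{path}: bad record at {rec.chrom}:{rec.pos}: {exc}") from exc
            gt_row, dp_row, gq_row, adr_row, ada_row = [], [], [], [], []
            for s in samples:
                fmt = rec.samples[s]
                alleles = fmt.get("GT", (None,))
                gt = _decompose_gt(tuple(alleles) if alleles is not None else (None,), k)
                ad = fmt.get("AD")
                ad_ref = ad_alt = ABSENT
                if ad is not None and len(ad) > k and ad[0] is not None and ad[k] is not None:
                    ad_ref, ad_alt = int(ad[0]), int(ad[k])
                dp = fmt.get("DP")
                if dp is None and ad_ref != ABSENT:
                    dp = ad_ref + ad_alt
                gq = fmt.get("GQ")
                gt_row.append(gt)
                dp_row.append(ABSENT if dp is None else int(dp))
                gq_row.append(ABSENT if gq is None else int(round(float(gq))))
                adr_row.append(ad_ref)
                ada_row.append(ad_alt)
            sites.append(key)
            rows_gt.append(gt_row)
            rows_dp.append(dp_row)
            rows_gq.append(gq_row)
            rows_adr.append(adr_row)
            rows_ada.append(ada_row)
    vf.close()

    n = len(sites)
    shape = (n, len(samples))
    return CohortTable(
        sites=sites,
        samples=samples,
        gt=np.array(rows_gt, dtype=np.int8).reshape(shape),
        dp=np.array(rows_dp, dtype=np.int32).reshape(shape),
        gq=np.array(rows_gq, dtype=np.int16).reshape(shape),
        ad_ref=np.array(rows_adr, dtype=np.int32).reshape(shape),
        ad_alt=np.array(rows_ada, dtype=np.int32).reshape(shape),
        source_label=source_label,
    )


def read_pedigree(path: str | Path) -> list[Trio]:
    """Parse a PLINK .fam file into the trios it defines.

    One :class:`Trio` is produced for each individual whose father and
    mother ids are both non-zero and defined in the file.  An individual
    listed as its own parent is an error; a parent id referenced but never
    defined produces a warning and the trio is skipped.
    """
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 whitespace-delimited columns")
            rows.append(tuple(parts[:6]))

    defined = {r[1] for r in rows}
    trios: list[Trio] = []
    for fam, iid, fid, mid, _sex, _phe in rows:
        if iid in (fid, mid):
            raise ValueError(f"individual {iid!r} listed as its own parent")
        if fid == "0" or mid == "0":
            continue
        if fid not in defined or mid not in defined:
            warnings.warn(
                f"trio for {iid!r} skipped: parent id not defined in {path}",
                stacklevel=2,
            )
            continue
        trios.append(Trio(child=iid, father=fid, mother=mid, family_id=fam))
    return trios


def read_fam_sexes(path: str | Path) -> dict[str, str]:
    """Sample -> sex label ('male'/'female'/'unknown') from a .fam file."""
    sexes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 6:
                sexes[parts[1]] = {"1": "male", "2": "female"}.get(parts[4], "unknown")
    return sexes


def restrict_to_autosomes(cohort: CohortTable) -> CohortTable:
    """Drop all X/Y sites (labels X, Y, chrX, chrY); order preserved."""
    keep = [i for i, k in enumerate(cohort.sites) if _normalize_chrom(k.chrom) not in SEX_CHROMS]
    return cohort.take_sites(keep)


def select_informative_sites(cohort: CohortTable, trio: Trio) -> CohortTable:
    """Drop sites where all three trio members are called hom_ref.

    Sites with any missing or non-reference trio genotype are retained: the
    all-reference rule only applies when every member is actually called.
    """
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt[:, [ic, ifa, imo]]
    all_homref = (g == HOM_REF).all(axis=1)
    return cohort.take_sites(~all_homref)


def write_vcf(cohort: CohortTable, path: str | Path, header_notes: Sequence[str] = ()) -> None:
    """Write the cohort as a VCF v4.2 file round-trippable by :func:`read_vcf`.

    Genotypes removed by filtering are emitted as missing with the reason
    recorded in the ``FR`` FORMAT subfield; ``header_notes`` (e.g. the
    applied thresholds) become ``##trioclean_*`` header lines.
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for i, note in enumerate(header_notes):
        header.add_line(f'##trioclean_note_{i}={note}')
    seen: list[str] = []
    for key in cohort.sites:
        if key.chrom not in seen:
            seen.append(key.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths for the ref and alt alleles")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add(FILTER_REASON_KEY, ".", "String",
                       "trioclean filter(s) that removed this genotype")
    for s in cohort.samples:
        header.add_sample(s)

    gt_alleles = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, key in enumerate(cohort.sites):
            rec = out.new_record(contig=key.chrom, start=key.pos - 1,
                                 alleles=(key.ref, key.alt))
            for j, s in enumerate(cohort.samples):
                fmt = rec.samples[s]
                fmt["GT"] = gt_alleles[int(cohort.gt[i, j])]
                if cohort.dp[i, j] != ABSENT:
                    fmt["DP"] = int(cohort.dp[i, j])
                if cohort.gq[i, j] != ABSENT:
                    fmt["GQ"] = int(cohort.gq[i, j])
                if cohort.ad_ref[i, j] != ABSENT and cohort.ad_alt[i, j] != ABSENT:
                    fmt["AD"] = (int(cohort.ad_ref[i, j]), int(cohort.ad_alt[i, j]))
                if cohort.filter_reason is not None and cohort.filter_reason[i, j]:
                    fmt[FILTER_REASON_KEY] = str(cohort.filter_reason[i, j])
            out.write(rec)
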