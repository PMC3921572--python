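"""Core data model: variant keys, genotype calls, cohort tables, trios.

A cohort is stored column-wise as numpy arrays over (site, sample) so that
the genotype-level filters and Mendelian classification vectorise; the
per-call :class:`GenotypeCall` view is materialised on demand.

Genotype categories are encoded as small integers (``HOM_REF``/``HET``/
``HOM_ALT``/``MISSING``); numeric FORMAT fields use ``-1`` as the
absent-value sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

# genotype category codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
GT_CODES = {v: k for k, v in GT_NAMES.items()}

#: sentinel for absent DP/GQ/AD values
ABSENT = -1


class VariantKey(NamedTuple):
    """Identity of one biallelic site (multi-allelics are decomposed)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"ref/alt must be non-empty and distinct: {self!r}")
        return self


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site: genotype category plus quality fields.

    ``dp`` is read depth, ``gq`` genotype quality (0-99), ``ad_ref``/``ad_alt``
    the reference/alternate supporting read counts; ``None`` means the field
    was absent from the VCF.
    """

    gt: int = MISSING
    dp: int | None = None
    gq: int | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None

    @property
    def gt_name(self) -> str:
        return GT_NAMES[self.gt]

    @property
    def is_called(self) -> bool:
        return self.gt != MISSING

    @property
    def is_nonref(self) -> bool:
        return self.gt in (HET, HOM_ALT)


@dataclass(frozen=True)
class Trio:
    """Child/father/mother sample identifiers for one family."""

    child: str
    father: str
    mother: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if len({self.child, self.father, self.mother}) != 3:
            raise ValueError(
                f"trio members must be distinct: {self.child}, {self.father}, {self.mother}"
            )

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.child, self.father, self.mother)


def _int_array(shape: tuple[int, int], dtype=np.int32) -> np.ndarray:
    return np.full(shape, ABSENT, dtype=dtype)


@dataclass
class CohortTable:
    """Variant sites x samples with per-genotype call records.

    Arrays are shaped ``(n_sites, n_samples)``; ``gt`` holds category codes
    and the numeric arrays hold ``ABSENT`` (-1) where the VCF field was
    missing.  ``filter_reason`` (object array of comma-joined codes, or
    ``None``) records why a genotype was set to missing by the filters.
    """

    sites: list[VariantKey]
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    source_label: str = ""
    filter_reason: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.sites), len(self.samples))
        for name in ("gt", "dp", "gq", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def empty(cls, sites: Sequence[VariantKey], samples: Sequence[str],
              source_label: str = "") -> "CohortTable":
        shape = (len(sites), len(samples))
        return cls(
            sites=list(sites),
            samples=list(samples),
            gt=_int_array(shape, np.int8),
            dp=_int_array(shape),
            gq=_int_array(shape, np.int16),
            ad_ref=_int_array(shape),
            ad_alt=_int_array(shape),
            source_label=source_label,
        )

    # -- indexed access -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in cohort {self.samples}") from None

    def trio_indices(self, trio: Trio) -> tuple[int, int, int]:
        return tuple(self.sample_index(s) for s in trio.members)  # type: ignore[return-value]

    def call(self, site: int | VariantKey, sample: int | str) -> GenotypeCall:
        """Materialise the :class:`GenotypeCall` at (site, sample)."""
        i = site if isinstance(site, int) else self.sites.index(site)
        j = sample if isinstance(sample, int) else self.sample_index(sample)

        def opt(arr: np.ndarray) -> int | None:
            v = int(arr[i, j])
            return None if v == ABSENT else v

        return GenotypeCall(
            gt=int(self.gt[i, j]),
            dp=opt(self.dp),
            gq=opt(self.gq),
            ad_ref=opt(self.ad_ref),
            ad_alt=opt(self.ad_alt),
        )

    def set_call(self, site: int | VariantKey, sample: int | str, call: GenotypeCall) -> None:
        i = site if isinstance(site, int) else self.sites.index(site)
        j = sample if isinstance(sample, int) else self.sample_index(sample)
        self.gt[i, j] = call.gt
        for name in ("dp", "gq", "ad_ref", "ad_alt"):
            v = getattr(call, name)
            getattr(self, name)[i, j] = ABSENT if v is None else v

    # -- subsetting -----------------------------------------------------------

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "CohortTable":
        """New cohort with the given site rows, order preserved."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortTable(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            gt=self.gt[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
            ad_ref=self.ad_ref[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
            source_label=self.source_label,
            filter_reason=None if self.filter_reason is None else self.filter_reason[idx].copy(),
        )

    def copy(self) -> "CohortTable":
        return self.take_sites(np.arange(self.n_sites))

    def site_index(self) -> dict[VariantKey, int]:
        return {k: i for i, k in enumerate(self.sites)}

    # -- equality (used by round-trip tests) ----------------------------------

    def equals(self, other: "CohortTable") -> bool:
        """Field-wise equality of sites, samples and all call arrays."""
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.gq, other.gq)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
        )


def count_child_variants(cohort: CohortTable, trio: Trio) -> int:
    """Variants counted for the child under the trio counting convention.

    A site counts when the child's genotype is called and at least one trio
    member carries a called non-reference genotype — so a variant whose
    parental genotypes were removed by filtering, with the child's call
    intact, still counts for the child.
    """
    ic, ifa, imo = cohort.trio_indices(trio)
    g = cohort.gt[:, [ic, ifa, imo]]
    child_called = g[:, 0] != MISSING
    any_nonref = ((g == HET) | (g == HOM_ALT)).any(axis=1)
    return int((child_called & any_nonref).sum())
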