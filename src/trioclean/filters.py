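"""Genotype-level quality filters: read depth, genotype quality, allele balance.

Three low-stringency filters, applied independently per genotype: a call is
removed (set to missing) when it fails *any* of them, and because each
predicate is evaluated on the original, pre-filter call, the result is
independent of application order by construction.

Defaults follow the recommended operating point for high-coverage exomes:
DP < 15 fails, GQ < 20 fails, and the alternate-allele-ratio window depends
on the called genotype (hom_ref fails above 0.15, hom_alt below 0.85, het
outside the open interval (0.3, 0.7)).  All inequalities are strict;
boundary values pass.  For cohorts under 75x mean coverage, the depth cutoff
adapts to 20% of the sample's mean depth instead of the 15-read hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .model import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortTable,
    GenotypeCall,
    Trio,
    count_child_variants,
)

FILTER_DP = "DP"
FILTER_GQ = "GQ"
FILTER_AB = "AB"
ALL_FILTERS = (FILTER_DP, FILTER_GQ, FILTER_AB)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and modes for the three genotype filters.

    ``adaptive_depth`` switches the depth cutoff to
    ``round(adaptive_fraction * mean_depth)`` when the sample's mean depth is
    at or below ``adaptive_mean_cutoff`` (75x).  ``max_dp`` exists for
    completeness but defaults to off: removing high-depth calls removes
    variants roughly at random rather than targeting errors.
    ``strict_missing`` flips the handling of absent DP/GQ/AD from pass
    (cannot fail on unavailable evidence) to fail.
    """

    min_dp: int = 15
    min_gq: int = 20
    het_ab_low: float = 0.3
    het_ab_high: float = 0.7
    homref_ab_max: float = 0.15
    homalt_ab_min: float = 0.85
    adaptive_depth: bool = True
    adaptive_mean_cutoff: float = 75.0
    adaptive_fraction: float = 0.20
    max_dp: int | None = None
    strict_missing: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.het_ab_low < self.het_ab_high <= 1):
            raise ValueError("require 0 <= het_ab_low < het_ab_high <= 1")
        if not (0 <= self.homref_ab_max < self.homalt_ab_min <= 1):
            raise ValueError("require 0 <= homref_ab_max < homalt_ab_min <= 1")
        if self.min_dp < 0:
            raise ValueError("min_dp must be >= 0")
        if not (0 <= self.min_gq <= 99):
            raise ValueError("min_gq must be in [0, 99]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def alt_allele_ratio(call: GenotypeCall) -> float | None:
    """Alternate-supporting reads over total allele-supporting reads.

    ``None`` (undefined) when AD is absent or both counts are zero.
    """
    if call.ad_ref is None or call.ad_alt is None:
        return None
    total = call.ad_ref + call.ad_alt
    if total == 0:
        return None
    return call.ad_alt / total


def depth_pass(call: GenotypeCall, min_dp: int, max_dp: int | None = None,
               strict_missing: bool = False) -> bool:
    """True when the call survives the depth filter (DP < min_dp fails)."""
    if call.dp is None:
        return not strict_missing
    if call.dp < min_dp:
        return False
    if max_dp is not None and call.dp > max_dp:
        return False
    return True


def genotype_quality_pass(call: GenotypeCall, min_gq: int,
                          strict_missing: bool = False) -> bool:
    """True when the call survives the GQ filter (GQ < min_gq fails)."""
    if call.gq is None:
        return not strict_missing
    return call.gq >= min_gq


def alt_ratio_pass(call: GenotypeCall, config: FilterConfig) -> bool:
    """Genotype-specific allele-balance window; boundary values pass.

    hom_ref fails when ratio > homref_ab_max; hom_alt fails when
    ratio < homalt_ab_min; het fails when ratio < het_ab_low or
    ratio > het_ab_high.  Missing genotypes pass vacuously; an undefined
    ratio passes unless ``strict_missing``.
    """
    if call.gt == MISSING:
        return True
    ratio = alt_allele_ratio(call)
    if ratio is None:
        return not config.strict_missing
    if call.gt == HOM_REF:
        return not ratio > config.homref_ab_max
    if call.gt == HOM_ALT:
        return not ratio < config.homalt_ab_min
    return not (ratio < config.het_ab_low or ratio > config.het_ab_high)


def resolve_depth_threshold(mean_depth: float, config: FilterConfig) -> int:
    """Effective min-DP for a sample given its mean read depth.

    Above 75x mean coverage the hard 15-read filter applies; at or below it,
    20% of the mean depth (rounded) is used instead — a hard filter on a
    low-coverage set would remove too many true variants.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not config.adaptive_depth or mean_depth > config.adaptive_mean_cutoff:
        return config.min_dp
    return int(round(config.adaptive_fraction * mean_depth))


@dataclass
class ExclusionAttribution:
    """Which filters each removed genotype failed, on the pre-filter cohort.

    ``fail`` maps filter name -> boolean array (n_sites, n_samples) over the
    *original* site order; ``sites``/``samples`` identify the axes.
    """

    sites: list
    samples: list[str]
    fail: dict[str, np.ndarray]

    def failed_filters(self, i: int, j: int) -> frozenset[str]:
        return frozenset(name for name in ALL_FILTERS if self.fail[name][i, j])

    def excluded_mask(self) -> np.ndarray:
        out = np.zeros_like(self.fail[FILTER_DP])
        for name in ALL_FILTERS:
            out |= self.fail[name]
        return out

    def n_excluded(self) -> int:
        return int(self.excluded_mask().sum())


def _fail_masks(cohort: CohortTable, config: FilterConfig) -> dict[str, np.ndarray]:
    """Vectorised per-genotype failure masks for the three filters.

    Only *called* genotypes can fail; missing genotypes pass vacuously.
    """
    called = cohort.gt != MISSING
    dp, gq = cohort.dp, cohort.gq
    adr, ada = cohort.ad_ref, cohort.ad_alt

    # per-sample effective depth threshold (adaptive rule); the mean is taken
    # over all present DP values so refiltering sees the same threshold
    dp_thresh = np.empty(len(cohort.samples))
    for j in range(len(cohort.samples)):
        present = dp[:, j] != ABSENT
        mean_depth = float(dp[present, j].mean()) if present.any() else float("inf")
        dp_thresh[j] = resolve_depth_threshold(mean_depth, config)

    dp_absent = dp == ABSENT
    fail_dp = np.where(dp_absent, config.strict_missing, dp < dp_thresh[None, :])
    if config.max_dp is not None:
        fail_dp |= (~dp_absent) & (dp > config.max_dp)

    gq_absent = gq == ABSENT
    fail_gq = np.where(gq_absent, config.strict_missing, gq < config.min_gq)

    ad_total = adr.astype(np.int64) + ada
    ab_defined = (adr != ABSENT) & (ada != ABSENT) & (ad_total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ab_defined, ada / np.maximum(ad_total, 1), np.nan)
    window_fail = np.zeros(cohort.gt.shape, dtype=bool)
    window_fail[cohort.gt == HOM_REF] = (ratio > config.homref_ab_max)[cohort.gt == HOM_REF]
    window_fail[cohort.gt == HOM_ALT] = (ratio < config.homalt_ab_min)[cohort.gt == HOM_ALT]
    het = cohort.gt == HET
    window_fail[het] = ((ratio < config.het_ab_low) | (ratio > config.het_ab_high))[het]
    fail_ab = np.where(ab_defined, window_fail, config.strict_missing)

    return {
        FILTER_DP: fail_dp & called,
        FILTER_GQ: fail_gq & called,
        FILTER_AB: fail_ab & called,
    }


def apply_filters(cohort: CohortTable, trio: Trio,
                  config: FilterConfig = FilterConfig()) -> tuple[CohortTable, ExclusionAttribution]:
    """Remove genotypes failing any filter; drop sites with nothing left.

    Every genotype failing at least one of the three predicates is set to
    missing (never altered to another called genotype) and all failed
    predicates are recorded in the attribution against the pre-filter
    cohort.  Sites left with no called non-reference genotype among the trio
    are dropped from the filtered cohort; the attribution keeps the original
    site axis.
    """
    masks = _fail_masks(cohort, config)
    attribution = ExclusionAttribution(sites=list(cohort.sites),
                                       samples=list(cohort.samples), fail=masks)
    excluded = attribution.excluded_mask()

    out = cohort.copy()
    out.gt = np.where(excluded, MISSING, out.gt).astype(np.int8)
    reasons = np.empty(out.gt.shape, dtype=object)
    reasons[:] = ""
    for name in ALL_FILTERS:
        m = masks[name]
        reasons[m] = np.where(reasons[m] == "", name, reasons[m] + "," + name)
    out.filter_reason = reasons

    ic, ifa, imo = out.trio_indices(trio)
    g = out.gt[:, [ic, ifa, imo]]
    keep = ((g == HET) | (g == HOM_ALT)).any(axis=1)
    return out.take_sites(keep), attribution


def filter_sweep(cohort: CohortTable, trio: Trio, axis: str,
                 grid: list[int]) -> list[dict]:
    """Variants and MEs remaining at increasingly stringent DP or GQ cutoffs.

    Other filters are off; each row reports the child-counting variants
    remaining and the Mendelian errors remaining at that threshold.
    """
    from .mendel import count_mendelian_errors

    if axis not in (FILTER_DP, FILTER_GQ):
        raise ValueError(f"axis must be {FILTER_DP!r} or {FILTER_GQ!r}")
    if sorted(grid) != list(grid):
        raise ValueError("grid must be sorted ascending")

    metric = cohort.dp if axis == FILTER_DP else cohort.gq
    called = cohort.gt != MISSING
    present = metric != ABSENT
    rows = []
    for threshold in grid:
        failing = called & present & (metric < threshold)
        sub = cohort.copy()
        sub.gt = np.where(failing, MISSING, sub.gt).astype(np.int8)
        summary = count_mendelian_errors(sub, trio)
        rows.append({
            "threshold": threshold,
            "variants_remaining": count_child_variants(sub, trio),
            "mendelian_errors_remaining": summary.n_errors,
        })
    return rows


def exclusion_venn(attribution: ExclusionAttribution) -> dict[frozenset, int]:
    """Genotype counts per non-empty filter subset (7 Venn regions).

    Each excluded genotype lands in exactly one region (the exact set of
    filters it failed); region counts therefore sum to the total excluded.
    """
    dp = attribution.fail[FILTER_DP]
    gq = attribution.fail[FILTER_GQ]
    ab = attribution.fail[FILTER_AB]
    code = dp.astype(np.int8) + 2 * gq.astype(np.int8) + 4 * ab.astype(np.int8)
    counts = np.bincount(code.ravel(), minlength=8)
    regions: dict[frozenset, int] = {}
    for c in range(1, 8):
        members = frozenset(
            name for bit, name in ((1, FILTER_DP), (2, FILTER_GQ), (4, FILTER_AB))
            if c & bit
        )
        regions[members] = int(counts[c])
    return regions


def venn_child_variants(attribution: ExclusionAttribution, cohort: CohortTable,
                        trio: Trio) -> dict[frozenset, int]:
    """Child-variant roll-up of the Venn: regions keyed by the child's call.

    Counts, per filter subset, the sites at which the *child's* genotype was
    excluded — a site-level companion to the genotype-level Venn for cohorts
    where "variants excluded" is read as child variants.
    """
    j = cohort.sample_index(trio.child)
    regions: dict[frozenset, int] = {
        k: 0 for k in exclusion_venn(attribution)
    }
    dp = attribution.fail[FILTER_DP][:, j]
    gq = attribution.fail[FILTER_GQ][:, j]
    ab = attribution.fail[FILTER_AB][:, j]
    for i in np.flatnonzero(dp | gq | ab):
        members = frozenset(
            name for flag, name in ((dp[i], FILTER_DP), (gq[i], FILTER_GQ), (ab[i], FILTER_AB))
            if flag
        )
        regions[members] += 1
    return regions
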