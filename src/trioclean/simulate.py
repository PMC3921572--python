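"""Synthetic trio exome cohorts with ground truth.

Generates father/mother/child genotype cohorts (optionally replicated over
several DNA "sources") whose artifact calls carry the empirical signatures
of real short-read exome trio data:

* read depth bimodal — artifacts peak near 5 reads, true calls near the
  target coverage (~100);
* genotype quality bimodal — a large artifact mass below GQ 20, true calls
  concentrated at 99;
* heterozygous allele-balance artifact peaks near 0.2 and 0.8, true hets
  binomial around 0.5.

Parental genotypes are Hardy-Weinberg draws at a per-site minor-allele
frequency; the child's genotype is Mendelian transmission; a configurable
number of sites are overridden to the de novo configuration (parents
hom_ref, child het).  Each remaining genotype independently becomes an
artifact with probability ``error_rate``; artifacts are *adjacent-category*
miscalls (hom -> het, het -> either hom), the allele-dropout / false-het
error modes of real callers — and the reason Mendelian errors under-detect
the true artifact burden by a factor of ~3 here, as they do in real trios.
Ground truth for every call is returned alongside the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

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

#: sample naming used by all simulated cohorts
DEFAULT_TRIO = Trio(child="CHILD", father="FATHER", mother="MOTHER", family_id="FAM1")
_SAMPLES = list(DEFAULT_TRIO.members)  # child, father, mother column order

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated trio cohort.

    Defaults emulate a ~50k-informative-site exome trio at ~100x coverage
    with a 3% per-genotype artifact probability and a handful of true de
    novo mutations.
    """

    n_sites: int = 50_000
    rare_site_fraction: float = 0.15   # point mass of rare sites in the MAF law
    rare_maf: float = 0.001
    maf_low: float = 0.01
    maf_high: float = 0.5
    error_rate: float = 0.03
    de_novo_count: int = 5
    mean_depth_true: float = 100.0
    depth_error_mode: float = 5.0
    low_depth_artifact_fraction: float = 0.7
    gq_error_mass_below_20: float = 0.7
    het_ab_error_peaks: tuple[float, float] = (0.2, 0.8)
    n_sources: int = 1
    n_x_sites: int = 0
    child_sex: str = "female"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rare_site_fraction", "error_rate", "gq_error_mass_below_20"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.de_novo_count > self.n_sites:
            raise ValueError("de_novo_count cannot exceed n_sites")
        if not all(0 < p < 1 for p in self.het_ab_error_peaks):
            raise ValueError("het_ab_error_peaks must lie in (0,1)")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for a simulated cohort.

    Arrays are (n_sites, 3) over [child, father, mother]; per-source
    artifact masks and observed genotypes are keyed by source label.
    ``is_de_novo`` flags sites carrying an injected de novo (true child het,
    true parents hom_ref, exempt from artifact injection).
    """

    sites: list[VariantKey]
    samples: list[str]
    sources: list[str]
    true_gt: np.ndarray
    is_de_novo: np.ndarray
    observed_gt: dict[str, np.ndarray] = field(default_factory=dict)
    is_artifact: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def de_novo_sites(self) -> list[VariantKey]:
        return [self.sites[i] for i in np.flatnonzero(self.is_de_novo)]


def _make_sites(rng: np.random.Generator, n: int, chroms: list[str],
                start_chrom_weighting: bool = True) -> list[VariantKey]:
    chrom_idx = np.sort(rng.integers(0, len(chroms), n))
    pos = rng.integers(1, 250_000_000, n)
    # resolve collisions per chromosome by sorting + cumulative bump
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    order = np.lexsort((pos, chrom_idx))
    sites = []
    used: set[tuple[int, int]] = set()
    for i in order:
        c, p = int(chrom_idx[i]), int(pos[i])
        while (c, p) in used:
            p += 1
        used.add((c, p))
        sites.append(VariantKey(chroms[c], p, str(_BASES[ref_i[i]]), str(_BASES[alt_i[i]])))
    return sites


def _true_genotypes(rng: np.random.Generator, params: SimulationParams) -> tuple:
    n = params.n_sites
    rare = rng.random(n) < params.rare_site_fraction
    maf = np.where(rare, params.rare_maf, rng.uniform(params.maf_low, params.maf_high, n))
    father = rng.binomial(2, maf)
    mother = rng.binomial(2, maf)
    child = (rng.random(n) < father / 2).astype(np.int8) + (
        rng.random(n) < mother / 2
    ).astype(np.int8)
    true = np.stack([child, father, mother], axis=1).astype(np.int8)

    is_dn = np.zeros(n, dtype=bool)
    if params.de_novo_count:
        dn = rng.choice(n, size=params.de_novo_count, replace=False)
        true[dn, :] = HOM_REF
        true[dn, 0] = HET
        is_dn[dn] = True
    return true, is_dn, maf


def _x_genotypes(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    """True X genotypes: father hemizygous, mother diploid, child by sex."""
    nx = params.n_x_sites
    maf = rng.uniform(params.maf_low, params.maf_high, nx)
    father_allele = (rng.random(nx) < maf).astype(np.int8)
    father = 2 * father_allele  # hemizygous calls emitted as hom
    mother = rng.binomial(2, maf).astype(np.int8)
    maternal = (rng.random(nx) < mother / 2).astype(np.int8)
    if params.child_sex == "male":
        child = 2 * maternal
    else:
        child = father_allele + maternal
    return np.stack([child, father, mother], axis=1).astype(np.int8)


def _corrupt(rng: np.random.Generator, true_gt: np.ndarray,
             exempt_rows: np.ndarray, error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent-category miscalls: hom -> het; het -> either hom."""
    is_artifact = rng.random(true_gt.shape) < error_rate
    is_artifact[exempt_rows, :] = False
    coin = rng.integers(0, 2, true_gt.shape)
    wrong = np.where(true_gt == HET,
                     np.where(coin == 0, HOM_REF, HOM_ALT),
                     HET).astype(np.int8)
    observed = np.where(is_artifact, wrong, true_gt).astype(np.int8)
    return observed, is_artifact


def _quality_fields(rng: np.random.Generator, observed: np.ndarray,
                    is_artifact: np.ndarray, params: SimulationParams):
    """DP/GQ/AD draws: true-call model vs artifact model, per genotype."""
    shape = observed.shape

    # artifact depth is a two-component mixture: most artifacts come from
    # too few reads (single-homolog sampling; depth near depth_error_mode),
    # the rest from misalignment of near-identical regions, which shows up
    # at ordinary coverage with a skewed allele balance instead
    dp = rng.poisson(params.mean_depth_true, shape)
    dp_art = np.where(
        rng.random(shape) < params.low_depth_artifact_fraction,
        rng.poisson(params.depth_error_mode, shape),
        rng.poisson(params.mean_depth_true, shape),
    )
    dp = np.where(is_artifact, dp_art, dp)
    dp = np.maximum(dp, 1).astype(np.int32)

    gq = 99 - np.minimum(rng.poisson(2.0, shape), 99)
    low = rng.integers(0, 20, shape)
    high = rng.integers(20, 100, shape)
    gq_art = np.where(rng.random(shape) < params.gq_error_mass_below_20, low, high)
    gq = np.where(is_artifact, gq_art, gq).astype(np.int16)

    # target alt-allele fraction per call, then an integer AD draw from it
    ab = np.select(
        [observed == HOM_REF, observed == HET, observed == HOM_ALT],
        [0.005, 0.5, 0.995],
    )
    p1, p2 = params.het_ab_error_peaks
    het_peak = np.where(rng.random(shape) < 0.65,
                        rng.normal(p1, 0.05, shape),
                        rng.normal(p2, 0.05, shape))
    ab_art = np.select(
        [observed == HOM_REF, observed == HET, observed == HOM_ALT],
        [rng.uniform(0.0, 0.45, shape), np.clip(het_peak, 0.02, 0.98),
         rng.uniform(0.55, 1.0, shape)],
    )
    ab = np.where(is_artifact, ab_art, ab)

    ad_alt = rng.binomial(dp, ab).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)
    return dp, gq, ad_ref, ad_alt


def _source_labels(n_sources: int) -> list[str]:
    named = ["blood", "buccal", "saliva"]
    if n_sources <= len(named):
        return named[:n_sources]
    return named + [f"source{i}" for i in range(4, n_sources + 1)]


def simulate_multisource(params: SimulationParams) -> tuple[dict[str, CohortTable], TruthTable]:
    """Simulate one trio sequenced from ``n_sources`` DNA sources.

    Truth (genotypes, de novo sites) is shared across sources; artifact
    injection and quality-field draws are independent per source, as they
    would be for independently prepared and sequenced libraries.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    sites = _make_sites(rng, params.n_sites, _AUTOSOMES)
    true_gt, is_dn, _maf = _true_genotypes(rng, params)
    if params.n_x_sites:
        sites = sites + _make_sites(rng, params.n_x_sites, ["chrX"])
        true_gt = np.vstack([true_gt, _x_genotypes(rng, params)])
        is_dn = np.concatenate([is_dn, np.zeros(params.n_x_sites, dtype=bool)])

    sources = _source_labels(params.n_sources)
    truth = TruthTable(sites=sites, samples=_SAMPLES, sources=sources,
                       true_gt=true_gt, is_de_novo=is_dn)
    cohorts: dict[str, CohortTable] = {}
    for src in sources:
        observed, is_artifact = _corrupt(rng, true_gt, is_dn, params.error_rate)
        dp, gq, ad_ref, ad_alt = _quality_fields(rng, observed, is_artifact, params)
        cohorts[src] = CohortTable(
            sites=list(sites), samples=list(_SAMPLES),
            gt=observed.copy(), dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=ad_alt,
            source_label=src,
        )
        truth.observed_gt[src] = observed
        truth.is_artifact[src] = is_artifact
    return cohorts, truth


def simulate_trio_cohort(params: SimulationParams) -> tuple[CohortTable, TruthTable]:
    """Single-source convenience wrapper around :func:`simulate_multisource`."""
    single = replace(params, n_sources=1)
    cohorts, truth = simulate_multisource(single)
    return next(iter(cohorts.values())), truth


@dataclass
class RecoveryMetrics:
    """How filtering treated artifact vs true calls, judged against truth."""

    n_artifact_calls: int
    n_artifact_removed: int
    n_true_calls: int
    n_true_retained: int
    n_de_novo: int
    n_de_novo_retained: int

    @property
    def artifact_sensitivity(self) -> float:
        """Fraction of artifact genotypes set to missing (or site-dropped)."""
        if self.n_artifact_calls == 0:
            return 0.0
        return self.n_artifact_removed / self.n_artifact_calls

    @property
    def true_call_retention(self) -> float:
        """Fraction of non-artifact called genotypes still called."""
        if self.n_true_calls == 0:
            return 0.0
        return self.n_true_retained / self.n_true_calls

    @property
    def de_novo_retention(self) -> float:
        if self.n_de_novo == 0:
            return 1.0
        return self.n_de_novo_retained / self.n_de_novo


def evaluate_against_truth(filtered: CohortTable, truth: TruthTable,
                           source: str | None = None,
                           baseline: CohortTable | None = None) -> RecoveryMetrics:
    """Score a filtered cohort against the simulator's ground truth.

    ``filtered`` must derive from the truth's cohort for ``source`` (the
    only source, when omitted); sites absent from the filtered cohort count
    as removed genotypes.  When ``baseline`` is given (typically the
    preprocessed cohort the filters ran on), only genotypes called there
    enter the denominators, so site-level preprocessing is not charged
    against the filters.
    """
    if source is None:
        if len(truth.sources) != 1:
            raise ValueError("source must be named for a multi-source truth")
        source = truth.sources[0]
    observed = truth.observed_gt[source]
    is_artifact = truth.is_artifact[source]

    site_pos = {k: i for i, k in enumerate(truth.sites)}
    try:
        rows = np.array([site_pos[k] for k in filtered.sites], dtype=int)
    except KeyError as exc:
        raise ValueError(f"filtered cohort contains a site unknown to the truth: {exc}")

    called_now = np.zeros(observed.shape, dtype=bool)
    if len(rows):
        called_now[rows] = filtered.gt != MISSING

    was_called = observed != MISSING  # simulator emits calls everywhere
    if baseline is not None:
        in_baseline = np.zeros(observed.shape, dtype=bool)
        base_rows = np.array([site_pos[k] for k in baseline.sites], dtype=int)
        if len(base_rows):
            in_baseline[base_rows] = baseline.gt != MISSING
        was_called &= in_baseline
    artifact_calls = is_artifact & was_called
    true_calls = ~is_artifact & was_called

    n_art = int(artifact_calls.sum())
    n_art_removed = int((artifact_calls & ~called_now).sum())
    n_true = int(true_calls.sum())
    n_true_kept = int((true_calls & called_now).sum())

    dn_rows = np.flatnonzero(truth.is_de_novo)
    n_dn_kept = 0
    filtered_index = {k: i for i, k in enumerate(filtered.sites)}
    for r in dn_rows:
        i = filtered_index.get(truth.sites[r])
        if i is not None and filtered.gt[i, 0] == HET:
            n_dn_kept += 1
    return RecoveryMetrics(
        n_artifact_calls=n_art,
        n_artifact_removed=n_art_removed,
        n_true_calls=n_true,
        n_true_retained=n_true_kept,
        n_de_novo=len(dn_rows),
        n_de_novo_retained=n_dn_kept,
    )


def synthesize_annotations(truth: TruthTable, seed: int = 0,
                           genes_per_chrom: int = 40,
                           altering_fraction: float = 0.6) -> "dict":
    """Synthetic annotation/AF table for a simulated cohort's sites.

    Genes are positional bins per chromosome; effects are drawn with
    ``altering_fraction`` amino-acid-altering mass; the population allele
    frequency mirrors each site's simulated frequency class.  Injected de
    novo sites are always nonsynonymous and novel (af 0), matching their
    role as ground-truth causal candidates.
    """
    from .inheritance import AMINO_ACID_ALTERING, AnnotationRecord

    rng = np.random.default_rng(seed)
    altering = sorted(AMINO_ACID_ALTERING)
    out: dict[VariantKey, AnnotationRecord] = {}
    for i, key in enumerate(truth.sites):
        gene_bin = key.pos * genes_per_chrom // 250_000_001
        gene = f"{key.chrom.upper()}_G{gene_bin:03d}"
        if truth.is_de_novo[i]:
            effect, af = "nonsynonymous", 0.0
        else:
            if rng.random() < altering_fraction:
                effect = altering[rng.integers(0, len(altering))]
            else:
                effect = "other"
            af = float(np.round(rng.uniform(0.0, 0.5), 4))
        out[key] = AnnotationRecord(key=key, gene=gene, effect=effect, af=af)
    return out


def write_annotation_tsv(annotations: dict, path) -> None:
    """Write an annotation dict in the TSV layout ``read_annotations`` reads."""
    import pandas as pd

    rows = [
        {"chrom": a.key.chrom, "pos": a.key.pos, "ref": a.key.ref, "alt": a.key.alt,
         "gene": a.gene, "effect": a.effect, "af_1kg": a.af, "af_esp": a.af,
         "af_internal": a.af}
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: TruthTable, path) -> None:
    """Dump the truth table (one row per site x sample x source) as TSV."""
    import pandas as pd

    from .model import GT_NAMES

    rows = []
    for src in truth.sources:
        obs = truth.observed_gt[src]
        art = truth.is_artifact[src]
        for i, key in enumerate(truth.sites):
            for j, sample in enumerate(truth.samples):
                rows.append({
                    "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                    "sample": sample, "source": src,
                    "true_gt": GT_NAMES[int(truth.true_gt[i, j])],
                    "observed_gt": GT_NAMES[int(obs[i, j])],
                    "is_artifact": bool(art[i, j]),
                    "is_de_novo": bool(truth.is_de_novo[i]) and sample == truth.samples[0],
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
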