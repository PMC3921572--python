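# Methods

## The Mendelian-error model

At a biallelic autosomal site, a child inherits one allele from each
parent.  Writing genotypes as alternate-allele counts (0 = hom-ref,
1 = het, 2 = hom-alt), the set of transmissible child genotypes is
`{a + b : a ∈ alleles(father), b ∈ alleles(mother)}`.  A fully called trio
genotype outside this set is a **Mendelian error**.  With exactly one
parental genotype missing, an error can still be inferred when the child
and the called parent are opposite homozygotes — no genotype of the missing
parent could make that transmissible.  A heterozygous child with only one
called parent is never evaluable (either missing-parent genotype could
explain it), and neither is a site with a missing child or two missing
parents.  Inferred errors are counted together with plain errors; the
engine reports one number.

The ME **rate** divides errors by the child's called variants under the
child-counting convention: a site counts for the child when the child's
genotype is called and at least one trio member carries a called
non-reference genotype.  Removing both parental genotypes with a filter
therefore does not remove the variant from the child's dataset.  Published
trio analyses report either this rate or close variants of it; where a
dataset motivates a different denominator the `MendelSummary` carries all
raw counts.

Mendelian errors under-detect artifacts.  An error in a genotype whose trio
configuration remains transmissible (e.g. a het miscalled hom-ref under het
× het parents) is invisible; empirically MEs flag roughly one-third to
one-quarter of true errors, and the simulator reproduces that gap (below).

## The three genotype filters

Each filter is a per-genotype predicate evaluated on the original call;
a genotype failing **any** predicate is set to missing (never rewritten to
another called genotype).  Because predicates never look at other
genotypes or at previous filter outcomes, composition is exactly
order-independent and idempotent, and the exclusion attribution (which
filters each removed genotype failed) is well defined against the
pre-filter cohort.

| filter | fails when | default | rationale |
|---|---|---|---|
| depth | DP < 15 (strict) | 15 reads | below ~15 reads, single-homolog sampling miscalls hets as homs at an appreciable rate |
| genotype quality | GQ < 20 (strict) | 20 | artifact calls concentrate in a low-GQ mode; true calls sit near 99 |
| allele balance | hom-ref: r > 0.15; hom-alt: r < 0.85; het: r < 0.3 or r > 0.7 (all strict) | — | read support should match the called genotype (r ≈ 0, 1, 0.5) |

Boundary values pass on every cutoff.  Calls with absent DP/GQ/AD pass the
corresponding predicate — a call cannot fail on unavailable evidence — and
a `strict_missing` flag flips that for sparse-FORMAT cohorts.  A high-depth
cutoff (`max_dp`) exists but is off by default: removing high-depth calls
removes variants roughly in proportion to their abundance rather than
targeting errors.

**Adaptive depth.**  In cohorts above 75× mean coverage the hard 15-read
filter applies; at or below 75× the cutoff becomes `round(0.2 × mean
depth)` (the two coincide exactly at 75×).  The mean is taken per sample
over all present DP values, not only over called genotypes: filtered
genotypes keep their DP, so the threshold — and hence the whole filter — is
stable under refiltering.  Restricting the mean to called genotypes would
let a second pass see a higher mean (the removed calls are low-depth) and
potentially a higher adaptive cutoff, breaking idempotence.

After genotype removal, sites left with no called non-reference genotype
among the trio are dropped: they carry no variant information for the
family.  The single-homolog expectation that motivates the depth cutoff is
computed as `n_sites × (1/2)^depth`.  First-principles probability that all
`d` reads sample one particular homolog of a het site is `2 × (1/2)^d =
(1/2)^(d-1)`; the implemented form is the convention used by the reference
operating points this package reproduces (≈50,000 at depth 10 and ≈1,500 at
depth 15 over 5×10⁷ sites), and the factor-of-two ambiguity does not affect
where the curve becomes negligible, which is what the cutoff is based on.

## Concordance and uniqueness

For one individual sequenced from two DNA sources, the **shared-only**
concordance is the fraction of identically called genotype categories among
sites called in both preprocessed cohorts; the **with-uniques** rate
additionally counts as discordant every site where the individual carries a
called non-reference genotype in exactly one source and no call in the
other.  A site called in both sources but discordantly (het vs hom-ref)
belongs to the shared denominator only — it is not double-counted as
unique.  With the same numerator and a larger denominator, the with-uniques
rate is never above the shared-only rate.

## Inheritance models

All three models run on the filtered cohort joined to an external
annotation table (annotation is consumed, never computed) and are
restricted to amino-acid-altering effects (nonsynonymous, splicing,
insertion, deletion, start/stop-codon change).  The effective population
allele frequency of a variant is the **maximum** over the provided
frequency columns — the conservative choice when filtering against several
databases — and a variant absent from the table is treated as novel
(AF = 0).

* *De novo*: child het, both parents called hom-ref.
* *Recessive homozygous*: child hom-alt, both parents het, AF < 0.01.
* *Compound heterozygous*: within a gene, a pair of child-het variants such
  that no single parent carries an alternate allele at both, with
  min(AF) < 0.01 and max(AF) ≤ 0.05.  "Up to 5%" is implemented as ≤ 0.05;
  both variants must be amino-acid-altering; a missing parental genotype at
  either site disqualifies the pair (a missing parent might carry both);
  phase is never consulted — the trio configuration alone constrains
  cis/trans, which also means a truly cis pair with each variant seen in a
  different parent cannot be excluded.

Cross-source intersection matches de novo and recessive candidates on the
variant key and compound-het candidates on (gene, variant pair).

## The synthetic trio generator

The generator emulates the *calls* of a trio exome experiment, not the
reads.  Per site, a minor-allele frequency is drawn from a mixture — with
probability 0.15 a rare site (MAF 0.001), otherwise uniform on
[0.01, 0.5] — parental genotypes are Hardy–Weinberg draws, and the child's
genotype is Mendelian transmission.  A configurable number of sites
(default 5) are overridden to the de novo configuration (parents hom-ref,
child het); these ground-truth positives are exempt from artifact
injection, so "all injected de novos recoverable" is a definition rather
than a random event.  Optional X-chromosome sites (hemizygous father,
diploid mother) support the sex-verification QC.

Every remaining genotype independently becomes an artifact with probability
`error_rate` (default 0.03), per source when several DNA sources are
simulated.  Corruption is **adjacent-category**: a hom is miscalled het and
a het is miscalled either hom (coin flip).  This is the physically sensible
error model — allele dropout and false-het misalignment; a hom-ref
miscalled hom-alt would require every read to be wrong — and it is what
produces the observed under-detection: at the defaults the simulated cohort
shows an unfiltered ME rate near 4% while ~9% of informative-site calls are
wrong, a detectability of ~0.29 per corrupted site, matching the
one-third-to-one-quarter rule.  A uniform choice among both wrong
categories instead yields ME rates of 7–10% and detectability ~0.5,
outside the regime the generator is meant to emulate.

Quality fields come from two models.  True calls: depth ~ Poisson(100), GQ
= 99 − min(Poisson(2), 99), alt-read count binomial at allele fraction
0.005 / 0.5 / 0.995 by genotype.  Artifacts: depth is a two-component
mixture — 70% low-depth (Poisson(5); single-homolog sampling) and 30% at
ordinary coverage (misalignment artifacts) — GQ places 70% of its mass
uniformly below 20, and the target allele balance is genotype-dependent
(het: peaks at 0.2/0.8 with weights 0.65/0.35, sd 0.05; hom-ref: uniform
0–0.45; hom-alt: uniform 0.55–1).  AD is an integer binomial draw at the
target fraction with `ad_ref + ad_alt = dp`, so allele-count conservation
holds exactly.  The depth mixture matters: at depth ~5 the read-count ratio
has granularity 1/5 and the 0.2/0.8 peaks are unresolvable, so a pure
low-depth artifact model cannot show the het allele-balance bimodality; the
ordinary-coverage component restores it, and also produces the realistic
handful of artifacts that survive all three filters.

**What the generator does not model:** read-level errors, sequence context,
capture bias, indel realignment, somatic mosaicism, linkage between sites,
and population structure.  Passing tests on simulated cohorts therefore
demonstrate the correctness and composition of the cleaning logic under a
stylised artifact process, not performance guarantees on any particular
real dataset — on real data the artifact depth/GQ/balance distributions,
and hence sensitivity and retention, will differ.

## Numerical and interface choices

* Multi-allelic records are decomposed into one biallelic record per
  alternate allele: het if exactly one allele index matches, hom-alt if
  both, hom-ref if neither and no allele is missing; `ad_ref` is the
  reference AD entry.  Half-calls (`./1`) are missing; phase separators are
  ignored; indels and SNVs are treated identically (all filters are
  genotype-metric based).  Absent DP with present AD is reconstructed as
  `ad_ref + ad_alt`.
* Autosome restriction removes chromosomes whose label normalises to X or Y
  (`X`, `chrX`, `Y`, `chrY`); informative-site selection removes sites
  where all three trio members are *called* hom-ref (a missing genotype
  retains the site).  Both operations are idempotent and commute.
* Filtered genotypes are written back to VCF as `./.` with the failed
  filters recorded in an `FR` FORMAT subfield, so a filtered VCF remains a
  valid, round-trippable VCF v4.2 that documents why each call was removed.
* QC defaults (configurable): a trio is flagged for an abundance of
  Mendelian errors above a 0.10 rate; X-heterozygosity below 0.05 is
  male-like and above 0.20 female-like for sex verification.  These
  cutoffs are this package's defaults; the checks themselves are standard
  upload sanity checks.
* The exclusion Venn counts **genotypes**; a child-variant roll-up
  (`venn_child_variants`) is provided alongside for site-level readings of
  "variants excluded".  Under the simulator's artifact model the three
  metrics of an artifact are corrupted jointly, so multi-filter Venn
  regions dominate; on real data, where single-metric failures are common,
  the single-filter regions are typically the majority.

## Test scales

The default test conditions are 50,000 sites for single-cohort recovery,
20,000 sites for the three-source concordance comparison, and 20 replicate
three-source simulations at 8,000 sites for de novo recovery — sizes at
which every acceptance-grade check runs in seconds while binomial noise on
the reported fractions stays well inside the asserted bands.
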