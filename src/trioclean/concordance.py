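"""Cross-DNA-source concordance for the same individual.

When one person is sequenced from two DNA sources (e.g. blood vs saliva),
genotype calls at shared sites should agree; disagreement and source-unique
variant calls are both dominated by sequencing artifacts, so concordance is
a second, filter-independent readout of data quality alongside the
Mendelian error rate.

Two rates are reported: *shared-only* (sites called in both sources) and
*with-uniques*, which additionally counts as discordant any site where the
sample carries a called non-reference genotype in exactly one source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HET, HOM_ALT, MISSING, CohortTable


@dataclass
class ConcordanceResult:
    sample: str
    source_a: str
    source_b: str
    n_shared_sites: int
    n_concordant: int
    n_unique_a: int
    n_unique_b: int

    @property
    def rate_shared_only(self) -> float:
        """Percent concordant among sites called in both sources."""
        if self.n_shared_sites == 0:
            return 100.0
        return 100.0 * self.n_concordant / self.n_shared_sites

    @property
    def rate_with_uniques(self) -> float:
        """Percent concordant when source-unique calls count as discordant."""
        denom = self.n_shared_sites + self.n_unique_a + self.n_unique_b
        if denom == 0:
            return 100.0
        return 100.0 * self.n_concordant / denom


def _sample_maps(cohort: CohortTable, sample: str):
    j = cohort.sample_index(sample)
    g = cohort.gt[:, j]
    called = {k: int(g[i]) for i, k in enumerate(cohort.sites) if g[i] != MISSING}
    nonref = {k for k, gt in called.items() if gt in (HET, HOM_ALT)}
    return called, nonref


def pair_concordance(cohort_a: CohortTable, cohort_b: CohortTable,
                     sample: str) -> ConcordanceResult:
    """Concordance of one sample's genotype calls between two cohorts.

    Both cohorts must be preprocessed identically (autosomes, informative
    sites for their respective trios).  Shared sites are those where the
    sample is called in both; a unique site is one where the sample carries
    a called non-reference genotype in one cohort and no call at all in the
    other (sites called in both, even discordantly, belong to the shared
    denominator only).
    """
    called_a, nonref_a = _sample_maps(cohort_a, sample)
    called_b, nonref_b = _sample_maps(cohort_b, sample)

    shared = set(called_a) & set(called_b)
    n_concordant = sum(1 for k in shared if called_a[k] == called_b[k])
    unique_a = sum(1 for k in nonref_a if k not in called_b)
    unique_b = sum(1 for k in nonref_b if k not in called_a)
    return ConcordanceResult(
        sample=sample,
        source_a=cohort_a.source_label or "a",
        source_b=cohort_b.source_label or "b",
        n_shared_sites=len(shared),
        n_concordant=n_concordant,
        n_unique_a=unique_a,
        n_unique_b=unique_b,
    )


def unique_variant_counts(cohorts: dict[str, CohortTable], sample: str) -> pd.DataFrame:
    """Source-unique non-reference calls for one sample, per source pair.

    Entry (s, t) counts sites where the sample has a called non-reference
    genotype in source ``s`` but not in source ``t``; the last column counts
    sites unique to ``s`` against all other sources jointly.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two sources")
    nonref = {src: _sample_maps(c, sample)[1] for src, c in cohorts.items()}
    sources = list(cohorts)
    rows = {}
    for s in sources:
        row = {}
        for t in sources:
            row[f"unique_vs_{t}"] = (
                np.nan if s == t else len(nonref[s] - nonref[t])
            )
        others = set().union(*(nonref[t] for t in sources if t != s))
        row["unique_vs_all_others"] = len(nonref[s] - others)
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def concordance_table(cohorts: dict[str, CohortTable], samples: list[str]) -> pd.DataFrame:
    """Per-sample, per-source-pair concordance rates as a tidy table."""
    sources = list(cohorts)
    records = []
    for i, a in enumerate(sources):
        for b in sources[i + 1:]:
            for sample in samples:
                r = pair_concordance(cohorts[a], cohorts[b], sample)
                records.append({
                    "source_pair": f"{a} vs {b}",
                    "sample": sample,
                    "rate_shared_only": r.rate_shared_only,
                    "rate_with_uniques": r.rate_with_uniques,
                    "n_shared_sites": r.n_shared_sites,
                    "n_unique_a": r.n_unique_a,
                    "n_unique_b": r.n_unique_b,
                })
    return pd.DataFrame.from_records(records)
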