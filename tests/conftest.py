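"""Shared fixtures: hand-built cohorts and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from trioclean import (
    DEFAULT_TRIO,
    CohortTable,
    GenotypeCall,
    SimulationParams,
    Trio,
    VariantKey,
    apply_filters,
    restrict_to_autosomes,
    select_informative_sites,
    simulate_multisource,
    simulate_trio_cohort,
)

TRIO = Trio(child="C", father="F", mother="M", family_id="F1")


def build_cohort(rows, samples=("C", "F", "M"), source_label="", chrom="chr1"):
    """Cohort from a list of per-site sample calls.

    ``rows`` is a list of either a dict {sample: GenotypeCall} or a tuple
    (VariantKey, {sample: GenotypeCall}); sites default to consecutive
    positions on ``chrom``.
    """
    sites, calls = [], []
    for i, row in enumerate(rows):
        if isinstance(row, tuple):
            key, mapping = row
        else:
            key, mapping = VariantKey(chrom, 100 + i, "A", "G"), row
        sites.append(key)
        calls.append(mapping)
    cohort = CohortTable.empty(sites, list(samples), source_label=source_label)
    for i, mapping in enumerate(calls):
        for sample, call in mapping.items():
            cohort.set_call(i, sample, call)
    return cohort


def gc(gt, dp=None, gq=None, ad=None):
    """Shorthand GenotypeCall constructor; ``ad`` is an (ad_ref, ad_alt) pair."""
    from trioclean.model import GT_CODES

    code = GT_CODES[gt] if isinstance(gt, str) else gt
    ad_ref, ad_alt = ad if ad is not None else (None, None)
    return GenotypeCall(gt=code, dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=ad_alt)


def preprocess(cohort, trio=DEFAULT_TRIO):
    return select_informative_sites(restrict_to_autosomes(cohort), trio)


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition trio cohort: 50k sites, 3% error, 5 de novos."""
    params = SimulationParams(seed=20140216)
    cohort, truth = simulate_trio_cohort(params)
    return params, cohort, truth


@pytest.fixture(scope="session")
def default_sim_filtered(default_sim):
    params, cohort, truth = default_sim
    pre = preprocess(cohort)
    filtered, attribution = apply_filters(pre, DEFAULT_TRIO)
    return pre, filtered, attribution


@pytest.fixture(scope="session")
def multisource_sim():
    """Three-source trio cohort collection with shared truth (20k sites)."""
    params = SimulationParams(seed=424242, n_sites=20_000, n_sources=3)
    cohorts, truth = simulate_multisource(params)
    return params, cohorts, truth
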