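"""Concordance between DNA sources, before and after filtering.

Simulates the same trio "sequenced" from blood, buccal and saliva DNA
(shared truth, independent artifacts) and shows that the genotype filters
push cross-source concordance from the mid-90s to ~100% while collapsing
source-unique variant calls.
"""

from trioclean import (
    DEFAULT_TRIO,
    SimulationParams,
    apply_filters,
    pair_concordance,
    restrict_to_autosomes,
    select_informative_sites,
    simulate_multisource,
    unique_variant_counts,
)

params = SimulationParams(seed=2, n_sites=20_000, n_sources=3)
cohorts, truth = simulate_multisource(params)

pre = {
    src: select_informative_sites(restrict_to_autosomes(c), DEFAULT_TRIO)
    for src, c in cohorts.items()
}
post = {src: apply_filters(c, DEFAULT_TRIO)[0] for src, c in pre.items()}

print("child concordance (shared-only / with-uniques), per source pair:")
pairs = [("blood", "buccal"), ("blood", "saliva"), ("buccal", "saliva")]
for a, b in pairs:
    r0 = pair_concordance(pre[a], pre[b], "CHILD")
    r1 = pair_concordance(post[a], post[b], "CHILD")
    print(f"  {a:6s} vs {b:6s}  unfiltered {r0.rate_shared_only:6.2f}% / "
          f"{r0.rate_with_uniques:6.2f}%   filtered {r1.rate_shared_only:6.2f}% / "
          f"{r1.rate_with_uniques:6.2f}%")

print("\nchild variants unique to one source (vs all others):")
u0 = unique_variant_counts(pre, "CHILD")["unique_vs_all_others"]
u1 = unique_variant_counts(post, "CHILD")["unique_vs_all_others"]
for src in u0.index:
    print(f"  {src:6s}  unfiltered {u0[src]:5d}   filtered {u1[src]:5d}")

# Source-unique calls are artifact-dominated: filtering removes nearly all
# of them, which is why mixed DNA sources remain usable for variant hunting.
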