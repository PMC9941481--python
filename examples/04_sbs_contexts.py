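"""SBS96 trinucleotide contexts of doublet components.

Contexts are written 5'[ref>alt]3' and canonicalised to the pyrimidine-centered
strand; two contexts are "the same" when identical or opposite-strand images.
A doublet whose components share a context hints at one mutational process
hitting the gene twice.
"""

from latentdoublet import (
    PlantedDoublet,
    SimulationConfig,
    canonical_context,
    doublet_context_summary,
    enumerate_candidates,
    enumerate_contexts,
    filter_cohort,
    generate_cohort,
    index_positions,
    same_context,
    test_candidates,
)

print(f"canonical alphabet: {len(enumerate_contexts())} contexts, e.g. {enumerate_contexts()[:3]}")
print(f"T[G>A]A canonicalises to {canonical_context('TGA', 'A').label}")
print(f"T[G>A]A same as T[C>T]A (opposite strands)? {same_context('T[G>A]A', 'T[C>T]A')}")

# a context-biased planted doublet: both components forced into T[C>T]A
planted = PlantedDoublet(
    "GENE000", 10, 20, joint=20, marginal_i=28, marginal_j=28, context="T[C>T]A"
)
cohort, _ = generate_cohort(SimulationConfig(n_samples=1500, planted_doublets=(planted,), seed=5))
filtered = filter_cohort(cohort)
doublets = test_candidates(enumerate_candidates(index_positions(filtered)), filtered)
summary, skipped = doublet_context_summary(doublets)
n_same = int(summary["same_context"].sum())
print(
    f"{len(summary)} (doublet, carrier) records with both components missense+context; "
    f"{n_same} share a context (skipped: {skipped})"
)
# With the planted doublet context-biased, every planted carrier record is
# same-context; background doublets (if any) are mostly different-context.
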