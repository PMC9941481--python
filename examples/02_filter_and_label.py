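"""Filter significant doublets and label their components.

After discovery, doublets are dropped when both components are nonsense,
when the N-terminal component is nonsense in most carriers, or when the
component VAFs never overlap; survivors carried by 3+ tumors are labeled
against a driver catalog: catalog members are known drivers (D), the rest
potential latent drivers (d), graded strong/weak by their frequency among
gene-mutant tumors (>10% for drivers, >1% for latent).
"""

from latentdoublet import (
    PlantedDoublet,
    SimulationConfig,
    annotate_doublet,
    apply_filters,
    enumerate_candidates,
    filter_cohort,
    gene_mutant_group,
    generate_cohort,
    generate_driver_catalog,
    index_positions,
    label_mutation,
    test_candidates,
)

planted = (
    PlantedDoublet("GENE000", 10, 20, joint=30, marginal_i=40, marginal_j=40, driver_i=True),
    PlantedDoublet("GENE001", 5, 30, joint=12, marginal_i=20, marginal_j=18),
)
cohort, truth = generate_cohort(SimulationConfig(n_samples=2000, planted_doublets=planted, seed=3))
catalog = set(map(tuple, generate_driver_catalog(truth).values))

filtered = filter_cohort(cohort)
index = index_positions(filtered)
doublets = test_candidates(enumerate_candidates(index), filtered)
stages = apply_filters(doublets)
print(
    f"{len(stages['input'])} significant -> {len(stages['significant'])} after filters, "
    f"{len(stages['prevalent'])} carried by 3+ tumors"
)

for d in stages["prevalent"]:
    group = gene_mutant_group(index, d.gene)
    li = label_mutation(d.pm_i, catalog, group)
    lj = label_mutation(d.pm_j, catalog, group)
    ann = annotate_doublet(d, li, lj)
    print(
        f"{d.gene} {d.pos_i}/{d.pos_j}: {ann.composition} ({li.strength} {li.driver_status} + "
        f"{lj.strength} {lj.driver_status}), {ann.cooccurrence}, classes {ann.class_pair}"
    )
# GENE000 has one cataloged component -> Dd; GENE001 has none -> dd.  Both are
# co-occurring (log2 OR > 0).  "Strong" latent drivers exceed 1% of their
# gene-mutant tumors.
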