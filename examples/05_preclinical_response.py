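"""Cell-line drug response and PDX growth for double vs single mutants.

Drug response z-scores are called sensitive (z < -2) / resistant (z > 2) /
gray otherwise.  A drug is interesting when it is gray in every single-mutant
line but significant in the double-mutant line, or when the call flips sign.
PDX tumor-volume curves are aligned to a 5-day grid by linear interpolation
so volume changes are comparable across models.
"""

from latentdoublet import (
    DrugResponse,
    GrowthCurve,
    PlantedDoublet,
    SimulationConfig,
    build_network,
    generate_cohort,
    generate_preclinical,
    interpolate_volume,
    select_drugs,
    volume_change,
)
from latentdoublet.preclinical import network_edge_list

planted = PlantedDoublet("GENE000", 10, 20, joint=30, marginal_i=40, marginal_j=40)
_, truth = generate_cohort(SimulationConfig(n_samples=500, planted_doublets=(planted,), seed=2))
lines, z, pdx = generate_preclinical(truth, seed=2)

dbl = [DrugResponse(r.cell_line, r.drug, r.z_score)
       for r in z.itertuples(index=False) if r.cell_line == "LINE_DOUBLE"]
sgl = [DrugResponse(r.cell_line, r.drug, r.z_score)
       for r in z.itertuples(index=False) if r.cell_line != "LINE_DOUBLE"]
selections = select_drugs(dbl, sgl, scheme="gray_to_significant_or_flip")
print("selected drugs (double-mutant-specific response):")
print(selections)

g = build_network(selections, {"LINE_DOUBLE": [f"GENE000:{p}" for p in (10, 20)]},
                  pathways_of_drugs={"DRUG_000": "PI3K/MTOR"})
print(network_edge_list(g))

for (model, treatment), grp in pdx.groupby(["model", "treatment"]):
    grp = grp.sort_values("timepoint_days")
    curve = GrowthCurve(model, treatment,
                        tuple(int(t) for t in grp.timepoint_days),
                        tuple(float(v) for v in grp.volume_mm3))
    interp = interpolate_volume(curve, grid_step=5)
    delta = volume_change(interp, 0, 10)
    print(f"{model:12s} {treatment:10s} volume change day 0->10: {delta:+9.1f} mm3")
# The double-mutant PDX grows fastest untreated and shrinks under treatment —
# the pattern expected if the doublet boosts oncogenic signalling and thereby
# drug dependence.
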