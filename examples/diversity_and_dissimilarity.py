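"""Shannon entropy, rarefied Bray-Curtis and intra/inter-patient grouping.

Simulates a cohort whose ascites samples differ compositionally from solid
sites, computes per-sample diversity, the rarefied dissimilarity matrix
(400 cells, 100 iterations) and compares intra- vs inter-patient pairs.
"""

import numpy as np

from tmeco.ecology import group_dissimilarity, rarefied_dissimilarity, shannon_entropy
from tmeco.synthetic import CohortDesign, EffectSpec, simulate_composition

n_patients = 8
sites = [["adnexa", "omentum", "ascites"]] * n_patients
design = CohortDesign(
    n_patients=n_patients,
    sites=sites,
    signatures=["HRD-Dup"] * 4 + ["FBI"] * 4,
    n_clusters=5,
    cells_per_sample=1500,
)
effects = EffectSpec.null(5, ["adnexa", "omentum", "ascites"], ["HRD-Dup", "FBI"])
effects.cluster_site[0, 2] = 2.0  # cluster_0 dominates ascites
table, _ = simulate_composition(design, effects, seed=4)

h = table.counts.apply(shannon_entropy, axis=1)
print("mean Shannon entropy (nats) by site:")
print(h.groupby(table.meta["site"]).mean().round(3))
# ascites entropy is lower: one cluster dominates there, solid sites stay
# near the 5-cluster maximum ln 5 = 1.609

dmat = rarefied_dissimilarity(table, n_cells=400, iterations=100, seed=0)
intra = group_dissimilarity(dmat, table.meta, scheme="intra_patient")
inter = group_dissimilarity(dmat, table.meta, scheme="inter_patient")
print(f"intra-patient pairs: n={len(intra)}, mean D={intra['d'].mean():.3f}")
print(f"inter-patient pairs: n={len(inter)}, mean D={inter['d'].mean():.3f}")

mixed = group_dissimilarity(
    dmat, table.meta, scheme="intra_patient", pair_filter=("site", "adnexa", "ascites")
)
solid = group_dissimilarity(
    dmat, table.meta, scheme="intra_patient", pair_filter=("site", "adnexa", "omentum")
)
print(f"adnexa-vs-ascites within patient: mean D={mixed['d'].mean():.3f} (n={len(mixed)})")
print(f"adnexa-vs-omentum within patient: mean D={solid['d'].mean():.3f} (n={len(solid)})")
# solid-solid pairs are nearly identical in composition (D ~ 0.05, the
# rarefaction noise floor) while solid-ascites pairs are far more dissimilar
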