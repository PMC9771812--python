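"""Fit a binomial-logit GLM of cluster composition with planted effects.

Simulates a 40-sample cohort in which cluster_1 is enriched (log2 OR = 1.5)
in HRD-Dup tumours, fits the composition GLM with cluster x site and
cluster x signature interactions, and prints the enrichment table.
"""

import numpy as np

from tmeco.composition import LN2, ModelSpec, enrichment_report, fit_composition_glm
from tmeco.synthetic import CohortDesign, EffectSpec, simulate_composition

n_patients = 20
design = CohortDesign(
    n_patients=n_patients,
    sites=[["adnexa", "omentum"]] * n_patients,
    signatures=["HRD-Dup"] * 10 + ["FBI"] * 10,
    n_clusters=4,
    cells_per_sample=2000,
)
effects = EffectSpec.null(4, ["adnexa", "omentum"], ["HRD-Dup", "FBI"])
effects.cluster_signature[1, 0] = 1.5 * LN2  # plant: cluster_1 enriched in HRD-Dup

table, truth = simulate_composition(design, effects, seed=1)
fit = fit_composition_glm(table, ModelSpec())
report = enrichment_report(fit)
print(report[["cluster", "level", "log2_or", "se", "p_adj"]].round(4).to_string(index=False))
# the (cluster_1, HRD-Dup) row recovers the planted log2 odds ratio of 1.5;
# the other clusters show the compensating depletion implied by composition
# summing to one, and site rows sit near zero (no site effect was planted).
# p_adj is Bonferroni-corrected over the reported interaction family.
print("family size:", report.attrs["family_size"])
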