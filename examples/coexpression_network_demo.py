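"""PD-1 / PD-L1 co-expression network across a small patient cohort.

Simulates sparse counts in which HRD patients co-express ligand (CD274 in
cancer cells) and receptor (PDCD1 in T cells) while FBI patients lack
receptor expression, then builds the per-group edge lists.
"""

import pandas as pd

from tmeco.network import build_network, expressing_fraction, patient_coexpression_flag
from tmeco.synthetic import simulate_expression_counts

GROUPS = {f"patient_{i:03d}": ("HRD-Dup" if i < 3 else "FBI") for i in range(6)}


def fractions(patient, cluster, gene):
    if cluster == "cancer" and gene == "CD274":
        return 0.30
    if cluster == "T" and gene == "PDCD1":
        return 0.30 if GROUPS[patient] == "HRD-Dup" else 0.02
    return 0.0


counts, meta, genes = simulate_expression_counts(
    6, ["cancer", "T"], ["CD274", "PDCD1LG2", "PDCD1"], fractions, cells_per_group=300, seed=0
)

sender = pd.concat(
    [expressing_fraction(counts, meta, genes, g) for g in ("CD274", "PDCD1LG2")]
)
receiver = expressing_fraction(counts, meta, genes, "PDCD1")
flags = patient_coexpression_flag(
    sender[sender["cluster"] == "cancer"], receiver[receiver["cluster"] == "T"]
)
print(flags)
# HRD-Dup patients co-express (ligand and receptor both >10% of cells);
# FBI patients fail the receptor threshold

edges = build_network(flags, GROUPS, min_patient_fraction=0.5)
print(edges.to_string(index=False))
# the cancer->T edge appears only in the HRD-Dup group (3/3 patients
# support it; 0/3 in FBI)
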