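import numpy as np
import pandas as pd
import pytest

from tmeco.core_tables import build_cluster_count_table
from tmeco.synthetic import ArmStateSpec, CohortDesign, EffectSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cell_table(rng):
    """A small synthetic cell table with QC metrics over 3 patients."""
    n = 600
    patients = rng.choice(["p1", "p2", "p3"], n)
    samples = [f"{p}_s{rng.integers(0, 2)}" for p in patients]
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": samples,
            "patient_id": patients,
            "site": ["adnexa" if s.endswith("s0") else "omentum" for s in samples],
            "sort_fraction": "CD45pos",
            "cluster": rng.choice(["T.naive", "T.dysfunctional", "NK"], n),
            "n_genes": rng.integers(100, 4000, n),
            "n_umi": rng.integers(200, 20000, n),
            "pct_mito": rng.uniform(0, 0.5, n),
            "doublet_score": rng.uniform(0, 0.5, n),
        }
    )


@pytest.fixture
def count_table(cell_table):
    return build_cluster_count_table(cell_table)


@pytest.fixture
def null_design():
    sites = [["adnexa", "omentum"] for _ in range(20)]
    signatures = ["HRD-Dup"] * 10 + ["FBI"] * 10
    return CohortDesign(
        n_patients=20, sites=sites, signatures=signatures, n_clusters=4, cells_per_sample=1000
    )


@pytest.fixture
def null_effects():
    return EffectSpec.null(4, ["adnexa", "omentum"], ["HRD-Dup", "FBI"])


@pytest.fixture
def loh_mixture_spec():
    """Half the cells carry 6p LOH; 17q stays balanced everywhere."""
    return ArmStateSpec(
        clone_states={
            "A": {"6p": "LOH", "17q": "balanced"},
            "B": {"6p": "balanced", "17q": "balanced"},
        },
        clone_fractions={"A": 0.5, "B": 0.5},
        n_cells=400,
        n_snps_per_arm=30,
        depth_per_snp=3.0,
    )
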