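"""Per-cell chromosome-arm B-allele fractions and LOH clonality.

SNP counts in single cells are far too sparse for per-SNP genotyping, so the
B allele is designated per SNP from the pseudobulk (the allele with the lower
aggregate frequency across cells) and counts are pooled over the SNPs of each
chromosome arm within each cell. Cells with at least ``min_reads`` reads on
an arm receive a BAF and an allelic state; sample-level LOH clonality is the
fraction of informative cancer cells in the LOH state.

State thresholds: balanced, BAF >= 0.35; imbalanced, 0.15 <= BAF < 0.35;
LOH, BAF < 0.15. Clonality: heterozygous, %LOH <= 20; subclonal,
20 < %LOH <= 80; clonal, %LOH > 80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

BAF_BALANCED_MIN = 0.35
BAF_IMBALANCED_MIN = 0.15
PCT_LOH_HET_MAX = 20.0
PCT_LOH_SUBCLONAL_MAX = 80.0


def _layer(adata: AnnData, name: str) -> sparse.csr_matrix:
    if name not in adata.layers:
        raise ValueError(f"allele count matrix lacks layer {name!r}")
    return sparse.csr_matrix(adata.layers[name])


def designate_b_allele(adata: AnnData, cells: np.ndarray | None = None) -> pd.DataFrame:
    """Choose the B allele per SNP from pseudobulk allele frequencies.

    Counts are summed over all cells (or the subset ``cells``, e.g. cancer
    cells only, for sensitivity analysis); the B allele is the minor allele,
    with exact 0.5 ties resolved to ``alt``. SNPs with zero reads are carried
    but flagged uninformative (B defaults to ``alt``).

    Returns a per-SNP table with columns ``b_allele`` in {"ref", "alt"} and
    ``informative``.
    """
    ref = _layer(adata, "ref")
    alt = _layer(adata, "alt")
    if cells is not None:
        ref, alt = ref[cells], alt[cells]
    ref_sum = np.asarray(ref.sum(axis=0)).ravel()
    alt_sum = np.asarray(alt.sum(axis=0)).ravel()
    total = ref_sum + alt_sum
    b_allele = np.where(alt_sum <= ref_sum, "alt", "ref")
    return pd.DataFrame(
        {"b_allele": b_allele, "informative": total > 0}, index=adata.var_names
    )


def cell_arm_baf(
    adata: AnnData, b_choice: pd.DataFrame, min_reads: int = 10
) -> pd.DataFrame:
    """Pool allele counts over each arm's SNPs to a per-(cell, arm) BAF table.

    ``b_count`` sums the designated B allele's reads, ``total_count`` all
    reads, over the SNPs mapped to the arm in ``adata.var['arm']``. The BAF
    ``b_count / total_count`` and an allelic state are emitted only for cells
    with ``total_count >= min_reads``; others are retained with state
    ``missing`` so denominators stay explicit.
    """
    if "arm" not in adata.var.columns:
        raise ValueError("SNP metadata must include an 'arm' column")
    ref = _layer(adata, "ref")
    alt = _layer(adata, "alt")
    b_is_alt = (b_choice.loc[adata.var_names, "b_allele"] == "alt").to_numpy()
    b_mat = alt.multiply(b_is_alt) + ref.multiply(~b_is_alt)
    total_mat = ref + alt
    rows = []
    for arm in pd.unique(adata.var["arm"]):
        cols = np.flatnonzero((adata.var["arm"] == arm).to_numpy())
        b = np.asarray(b_mat[:, cols].sum(axis=1)).ravel()
        t = np.asarray(total_mat[:, cols].sum(axis=1)).ravel()
        informative = t >= min_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            baf = np.where(informative, b / np.where(t > 0, t, 1), np.nan)
        state = np.where(informative, classify_allelic_state(np.nan_to_num(baf)), "missing")
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": adata.obs_names,
                    "arm": arm,
                    "b_count": b.astype(np.int64),
                    "total_count": t.astype(np.int64),
                    "baf": baf,
                    "state": state,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def classify_allelic_state(baf):
    """Map BAF values onto {balanced, imbalanced, LOH}.

    Balanced for BAF >= 0.35, imbalanced for 0.15 <= BAF < 0.35, LOH below
    0.15. Accepts scalars or arrays; values outside [0, 1] are an error.
    """
    arr = np.asarray(baf, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("BAF must lie in [0, 1]")
    out = np.where(arr >= BAF_BALANCED_MIN, "balanced",
                   np.where(arr >= BAF_IMBALANCED_MIN, "imbalanced", "LOH"))
    return out if arr.ndim else str(out)


@dataclass
class LohSummary:
    """Sample-level LOH burden among informative cancer cells."""

    pct_loh: float
    clonality: str
    n_cells_informative: int


def sample_loh_summary(
    baf_table: pd.DataFrame,
    cell_types: pd.Series,
    arm: str = "6p",
    cancer_label: str = "cancer",
) -> LohSummary:
    """Percentage of LOH cancer cells on an arm and the implied clonality.

    Only cancer cells (per ``cell_types``, indexed by cell id) with an
    informative BAF on ``arm`` enter the denominator. Clonality:
    heterozygous (<= 20%), subclonal (20, 80], clonal (> 80%).
    """
    sub = baf_table[baf_table["arm"] == arm]
    types = sub["cell_id"].map(cell_types)
    informative = sub[(types == cancer_label) & (sub["state"] != "missing")]
    if len(informative) == 0:
        raise ValueError(f"no informative {cancer_label} cells on arm {arm}")
    pct = 100.0 * float((informative["state"] == "LOH").mean())
    if pct <= PCT_LOH_HET_MAX:
        clonality = "heterozygous"
    elif pct <= PCT_LOH_SUBCLONAL_MAX:
        clonality = "subclonal"
    else:
        clonality = "clonal"
    return LohSummary(pct_loh=pct, clonality=clonality, n_cells_informative=len(informative))


def read_arm_bed(path) -> pd.DataFrame:
    """Read a BED arm map (0-based half-open) into 1-based inclusive bounds."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "arm"], dtype={"chrom": str}
    )
    bed["start"] = bed["start"].astype(np.int64) + 1  # 1-based inclusive start
    bed["end"] = bed["end"].astype(np.int64)  # half-open end == inclusive end
    return bed


def assign_arms(snps: pd.DataFrame, arm_map: pd.DataFrame) -> pd.Series:
    """Map SNPs (1-based ``chrom``/``pos``) onto arms from a converted BED map."""
    arms = pd.Series(pd.NA, index=snps.index, dtype="object")
    for _, row in arm_map.iterrows():
        hit = (
            (snps["chrom"].astype(str) == str(row["chrom"]))
            & (snps["pos"] >= row["start"])
            & (snps["pos"] <= row["end"])
        )
        arms[hit] = row["arm"]
    return arms
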