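"""Canonical data model, I/O and cell-level quality control.

Cells are represented as rows of a :class:`pandas.DataFrame` with the columns in
:data:`CELL_COLUMNS`; per-sample cluster counts are held in a
:class:`ClusterCountTable` (samples x clusters contingency plus sample metadata).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical cell-table columns. QC metrics are only required by the QC filter.
CELL_COLUMNS = (
    "cell_id",
    "sample_id",
    "patient_id",
    "site",
    "sort_fraction",
    "cluster",
)

#: QC metric columns required by :func:`filter_cells_qc`.
QC_COLUMNS = ("n_genes", "n_umi", "pct_mito", "doublet_score")

SITES = ("adnexa", "omentum", "peritoneum", "bowel", "ascites", "other")
SORT_FRACTIONS = ("CD45pos", "CD45neg", "unsorted")
SIGNATURES = ("HRD-Dup", "HRD-Del", "FBI", "TD", "Undetermined")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds.

    Cells are kept when ``n_genes >= min_genes``, ``n_umi >= min_umi``,
    ``pct_mito < max_pct_mito`` and ``doublet_score <= max_doublet``.
    """

    min_genes: int = 500
    min_umi: int = 1000
    max_pct_mito: float = 0.25
    max_doublet: float = 0.25

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("count thresholds must be strictly positive")
        if not (0 < self.max_pct_mito <= 1) or not (0 < self.max_doublet <= 1):
            raise ValueError("fraction thresholds must lie in (0, 1]")


def filter_cells_qc(cells: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Apply per-cell QC, preserving the input row order.

    Parameters
    ----------
    cells
        Cell table containing the :data:`QC_COLUMNS` metrics.
    thresholds
        Retention thresholds; defaults to :class:`QCThresholds`.

    Returns
    -------
    The retained rows. A log line reports the number of cells failing each
    criterion (a cell may fail several).
    """
    thr = thresholds or QCThresholds()
    missing = [c for c in QC_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"QC columns missing from cell table: {missing}")
    if len(cells) == 0:
        warnings.warn("filter_cells_qc received an empty cell table", stacklevel=2)
        return cells.copy()
    qc = cells[list(QC_COLUMNS)]
    if not all(pd.api.types.is_numeric_dtype(qc[c]) for c in QC_COLUMNS):
        raise TypeError("QC columns must be numeric")

    fails = {
        "n_genes": cells["n_genes"] < thr.min_genes,
        "n_umi": cells["n_umi"] < thr.min_umi,
        "pct_mito": cells["pct_mito"] >= thr.max_pct_mito,
        "doublet_score": cells["doublet_score"] > thr.max_doublet,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    logger.info(
        "filter_cells_qc: kept %d/%d cells (removed per criterion: %s)",
        int(keep.sum()),
        len(cells),
        {k: int(v.sum()) for k, v in fails.items()},
    )
    return cells.loc[keep].copy()


def cluster_relative_entropy(cells: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Score each cluster by the evenness of its patient composition.

    For each cluster the empirical Shannon entropy (natural log) of its patient
    composition is divided by the maximum attainable entropy, ``log`` of the
    number of patients in the whole cohort. Clusters with a relative entropy
    below ``threshold`` are dominated by few patients and flagged
    ``patient_specific``.

    Returns a table indexed by cluster with columns ``relative_entropy`` and
    ``patient_specific``.
    """
    for col in ("cluster", "patient_id"):
        if col not in cells.columns:
            raise ValueError(f"column {col!r} required")
    n_patients = cells["patient_id"].nunique()
    if n_patients < 2:
        raise ValueError("relative entropy is undefined for a single-patient cohort")
    max_h = np.log(n_patients)

    def _rel_entropy(patients: pd.Series) -> float:
        p = patients.value_counts(normalize=True).to_numpy()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / max_h)

    rel = cells.groupby("cluster", observed=True)["patient_id"].agg(_rel_entropy)
    out = rel.rename("relative_entropy").to_frame()
    out["patient_specific"] = out["relative_entropy"] < threshold
    return out


@dataclass
class ClusterCountTable:
    """Per-sample cluster counts with per-sample metadata.

    ``counts`` is a samples x clusters integer DataFrame; ``meta`` is indexed by
    the same samples and carries covariates such as site, signature, patient,
    sort fraction or region.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("cluster counts must be non-negative")
        if not self.meta.empty and not self.meta.index.equals(counts.index):
            self.meta = self.meta.reindex(counts.index)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def clusters(self) -> pd.Index:
        return self.counts.columns

    def totals(self) -> pd.Series:
        """Row totals N per sample."""
        return self.counts.sum(axis=1)

    def to_long(self) -> pd.DataFrame:
        """Long form with one row per (sample, cluster) plus metadata and totals."""
        long = (
            self.counts.stack()
            .rename("n_c")
            .reset_index()
            .set_axis(["sample_id", "cluster", "n_c"], axis=1)
        )
        long = long.merge(
            self.totals().rename("n_total"), left_on="sample_id", right_index=True
        )
        if not self.meta.empty:
            long = long.merge(self.meta, left_on="sample_id", right_index=True)
        return long

    def write_tsv(self, path) -> None:
        self.counts.join(self.meta).to_csv(path, sep="\t", index_label="sample_id")


def build_cluster_count_table(
    cells: pd.DataFrame,
    sample_col: str = "sample_id",
    cluster_col: str = "cluster",
    meta_cols: tuple[str, ...] = ("patient_id", "site", "sort_fraction"),
) -> ClusterCountTable:
    """Tabulate cells into a (sample x cluster) contingency with metadata.

    Clusters absent from a sample are zero-filled; the table conserves the
    total cell count. Metadata must be constant within a sample.
    """
    if cluster_col not in cells.columns:
        raise ValueError(f"column {cluster_col!r} required")
    counts = pd.crosstab(cells[sample_col], cells[cluster_col])
    counts.index.name = "sample_id"
    counts.columns.name = "cluster"

    present = [c for c in meta_cols if c in cells.columns]
    meta = cells.groupby(sample_col, observed=True)[present].agg(pd.unique) if present else pd.DataFrame(index=counts.index)
    for col in present:
        bad = meta[col].map(lambda v: np.size(v) != 1)
        if bad.any():
            raise ValueError(
                f"metadata column {col!r} is not constant within samples: "
                f"{list(meta.index[bad])}"
            )
        meta[col] = meta[col].map(lambda v: np.asarray(v).ravel()[0])
    return ClusterCountTable(counts=counts, meta=meta)


def read_cell_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited cell table and validate categorical vocabularies."""
    cells = pd.read_csv(path, sep=sep)
    missing = [c for c in ("cell_id", "sample_id", "cluster") if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    if "site" in cells.columns:
        bad = set(cells["site"].dropna()) - set(SITES)
        if bad:
            raise ValueError(f"unknown site labels: {sorted(bad)}")
    if "sort_fraction" in cells.columns:
        bad = set(cells["sort_fraction"].dropna()) - set(SORT_FRACTIONS)
        if bad:
            raise ValueError(f"unknown sort fractions: {sorted(bad)}")
    return cells
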