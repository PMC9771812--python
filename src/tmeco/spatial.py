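"""mpIF phenotype gating and spatial topology statistics.

Cells arrive as tables of centroid coordinates (µm) and mean marker
intensities per field of view (FOV). Gating turns intensities into phenotype
labels (objects positive for several lineage markers are emitted once per
lineage); spatial statistics comprise signed distance to the tumour-stroma
interface, 10 µm band density profiles with binomial standard errors,
per-cell nearest-neighbour distances and fixed-radius proximity counts.
All distances are FOV-local and exact (no stitching, no approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from tmeco.synthetic import signed_boundary_distance

logger = logging.getLogger(__name__)

LINEAGE_MARKERS = ("panCK", "CD68", "CD8")


@dataclass
class GateSpec:
    """Per-marker positivity thresholds and phenotype definitions.

    ``phenotypes`` maps a label to required marker states, e.g.
    ``{"CD8+PD-1+TOX-": {"CD8": True, "PD1": True, "TOX": False}}``. Each
    definition must reference exactly one positive lineage marker; all
    referenced markers must have thresholds.
    """

    thresholds: Mapping[str, float]
    phenotypes: Mapping[str, Mapping[str, bool]]
    lineage_markers: tuple[str, ...] = LINEAGE_MARKERS

    def __post_init__(self) -> None:
        for name, definition in self.phenotypes.items():
            missing = [m for m in definition if m not in self.thresholds]
            if missing:
                raise ValueError(f"phenotype {name!r} references ungated markers: {missing}")

    def lineage_of(self, name: str) -> str | None:
        for marker in self.lineage_markers:
            if self.phenotypes[name].get(marker):
                return marker
        return None


def gate_phenotypes(cells: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Assign phenotype labels from marker intensities.

    Marker positivity is ``intensity >= threshold``. A segmented object
    positive for several lineage markers is emitted once per lineage at the
    same coordinates. Within a lineage, the most specific matching phenotype
    definition wins; cells positive for no lineage marker are labelled
    ``other``.
    """
    positive = pd.DataFrame(
        {m: cells[m] >= thr for m, thr in gates.thresholds.items() if m in cells.columns}
    )
    missing = [m for m in gates.thresholds if m not in cells.columns]
    if missing:
        raise ValueError(f"intensity columns missing for gated markers: {missing}")

    by_lineage: dict[str, list[str]] = {}
    for name in gates.phenotypes:
        lineage = gates.lineage_of(name)
        if lineage is not None:
            by_lineage.setdefault(lineage, []).append(name)

    records = []
    for i in range(len(cells)):
        pos = positive.iloc[i]
        lineages = [m for m in gates.lineage_markers if pos.get(m, False)]
        if not lineages:
            records.append((i, "other"))
            continue
        for lineage in lineages:
            label = lineage + "+"
            best = -1
            for name in by_lineage.get(lineage, ()):
                definition = gates.phenotypes[name]
                if all(pos.get(m, False) == want for m, want in definition.items()):
                    if len(definition) > best:
                        best, label = len(definition), name
            records.append((i, label))
    idx = [i for i, _ in records]
    out = cells.iloc[idx].copy().reset_index(drop=True)
    out["phenotype"] = [label for _, label in records]
    return out


@dataclass
class BoundaryGeometry:
    """Per-FOV tumour polygons; the polygon boundary is the interface."""

    tumour: Mapping[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fov, poly in self.tumour.items():
            if poly.boundary.length == 0:
                raise ValueError(f"degenerate boundary for FOV {fov!r}")


def boundary_distance(cells: pd.DataFrame, geometry: BoundaryGeometry) -> pd.DataFrame:
    """Signed distance (µm) to the tumour-stroma interface per cell.

    Positive on the tumour side, negative in the stroma. Cells in FOVs
    without geometry get ``NaN`` and are flagged in the log.
    """
    out = cells.copy()
    out["signed_distance"] = np.nan
    n_missing = 0
    for fov, grp in cells.groupby("fov_id", observed=True):
        poly = geometry.tumour.get(fov)
        if poly is None:
            n_missing += len(grp)
            continue
        out.loc[grp.index, "signed_distance"] = signed_boundary_distance(
            grp["x"].to_numpy(), grp["y"].to_numpy(), poly
        )
    if n_missing:
        logger.warning("boundary_distance: %d cells in FOVs without geometry", n_missing)
    return out


def density_profile(
    cells: pd.DataFrame,
    phenotype: str,
    band_width: float = 10.0,
    se_mode: str = "band_total",
) -> pd.DataFrame:
    """Phenotype density by signed distance band, pooled across FOVs.

    Cells are binned into half-open bands ``[k*w, (k+1)*w)`` of signed
    boundary distance; the phenotype's counts are normalized by its total so
    the densities sum to 1. The standard error is the binomial
    ``sqrt(p(1-p)/N)``: with ``se_mode='band_total'`` (default) ``p`` is the
    phenotype's share of all cells in the band and ``N`` the band's total
    cell count; ``'phenotype_total'`` instead uses the plotted density with
    ``N`` the phenotype total.
    """
    if "signed_distance" not in cells.columns:
        raise ValueError("run boundary_distance first (signed_distance column missing)")
    valid = cells.dropna(subset=["signed_distance"])
    is_pheno = valid["phenotype"] == phenotype
    n_pheno = int(is_pheno.sum())
    if n_pheno == 0:
        raise ValueError(f"phenotype {phenotype!r} absent from the cell table")
    band = np.floor(valid["signed_distance"] / band_width).astype(int)
    lo, hi = band.min(), band.max()
    index = pd.RangeIndex(lo, hi + 1)
    n_band = band.value_counts().reindex(index, fill_value=0)
    k_band = band[is_pheno].value_counts().reindex(index, fill_value=0)
    density = k_band / n_pheno
    if se_mode == "band_total":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (k_band / n_band).to_numpy()
        n = n_band.to_numpy(dtype=float)
    elif se_mode == "phenotype_total":
        p = density.to_numpy()
        n = float(n_pheno)
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    with np.errstate(invalid="ignore"):
        se = np.sqrt(p * (1 - p) / np.where(np.asarray(n) > 0, n, np.nan))
    return pd.DataFrame(
        {
            "band_start": index * band_width,
            "band_end": (index + 1) * band_width,
            "n_phenotype": k_band.to_numpy(),
            "n_band": n_band.to_numpy(),
            "density": density.to_numpy(),
            "se": se,
        }
    )


def nn_distances(
    cells: pd.DataFrame, source_phenotype: str, target_phenotype: str
) -> pd.DataFrame:
    """Per-source-cell distance (µm) to the nearest target cell, within FOV.

    When source and target phenotypes coincide, each cell is excluded from
    its own target set (distance to the nearest *other* cell). Source cells
    in FOVs lacking any target get ``NaN`` and a logged count; summaries
    should drop them.
    """
    results = []
    n_no_target = 0
    for fov, grp in cells.groupby("fov_id", observed=True):
        src = grp[grp["phenotype"] == source_phenotype]
        tgt = grp[grp["phenotype"] == target_phenotype]
        if src.empty:
            continue
        if tgt.empty:
            results.append(
                pd.DataFrame(
                    {"cell_id": src["cell_id"], "fov_id": fov, "nn_distance": np.nan}
                )
            )
            n_no_target += len(src)
            continue
        tree = cKDTree(tgt[["x", "y"]].to_numpy(dtype=float))
        same = source_phenotype == target_phenotype
        k = 2 if same and len(tgt) > 1 else 1
        dist, idx = tree.query(src[["x", "y"]].to_numpy(dtype=float), k=k)
        if same:
            if len(tgt) == 1:
                # the lone target is the source itself: no other cell exists
                d = np.full(len(src), np.nan)
                n_no_target += len(src)
            else:
                tgt_pos = {cid: j for j, cid in enumerate(tgt["cell_id"])}
                self_j = src["cell_id"].map(tgt_pos).to_numpy()
                is_self = idx[:, 0] == np.where(pd.isna(self_j), -1, self_j)
                d = np.where(is_self, dist[:, 1], dist[:, 0])
        else:
            d = np.atleast_1d(dist) if k == 1 else dist[:, 0]
        results.append(pd.DataFrame({"cell_id": src["cell_id"], "fov_id": fov, "nn_distance": d}))
    if n_no_target:
        logger.warning("nn_distances: %d source cells without any target", n_no_target)
    if not results:
        return pd.DataFrame(columns=["cell_id", "fov_id", "nn_distance"])
    return pd.concat(results, ignore_index=True)


def nn_summary(distances: pd.DataFrame) -> pd.DataFrame:
    """Median nearest-neighbour distance per FOV plus a pooled row."""
    valid = distances.dropna(subset=["nn_distance"])
    per_fov = (
        valid.groupby("fov_id", observed=True)["nn_distance"]
        .agg(median="median", n="size")
        .reset_index()
    )
    pooled = pd.DataFrame(
        {
            "fov_id": ["pooled"],
            "median": [valid["nn_distance"].median()],
            "n": [len(valid)],
        }
    )
    return pd.concat([per_fov, pooled], ignore_index=True)


def proximity_counts(
    cells: pd.DataFrame,
    source_phenotype: str,
    target_phenotype: str,
    radius: float = 30.0,
) -> pd.DataFrame:
    """Source cells with >= 1 target within ``radius`` µm, per FOV and pooled.

    Built on nearest-neighbour distances (a source is proximal iff its NN
    distance is <= radius); also reports the proximal fraction and its
    complement among sources with a defined neighbour.
    """
    nnd = nn_distances(cells, source_phenotype, target_phenotype)
    rows = []
    for fov, grp in nnd.groupby("fov_id", observed=True):
        valid = grp.dropna(subset=["nn_distance"])
        prox = int((valid["nn_distance"] <= radius).sum())
        frac = prox / len(valid) if len(valid) else np.nan
        rows.append(
            {
                "fov_id": fov,
                "n_source": len(grp),
                "n_proximal": prox,
                "fraction_proximal": frac,
                "fraction_distal": 1 - frac if len(valid) else np.nan,
            }
        )
    valid = nnd.dropna(subset=["nn_distance"])
    prox = int((valid["nn_distance"] <= radius).sum())
    frac = prox / len(valid) if len(valid) else np.nan
    rows.append(
        {
            "fov_id": "pooled",
            "n_source": len(nnd),
            "n_proximal": prox,
            "fraction_proximal": frac,
            "fraction_distal": 1 - frac if len(valid) else np.nan,
        }
    )
    return pd.DataFrame(rows)
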