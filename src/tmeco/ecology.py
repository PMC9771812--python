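"""Diversity and dissimilarity of cluster composition, and embedding ecology.

Implements Shannon entropy of cluster proportions, the Bray-Curtis
dissimilarity ``D = 1 - 2 sum_c min(N_c^i, N_c^j) / (sum_c N_c^i + sum_c
N_c^j)`` with rarefaction (repeated subsampling to a fixed cell count),
intra-/inter-patient grouping of the averaged distance matrix, pairwise KDE
enrichment fields in a 2-D embedding, and per-cell patient-specificity scores
on a kNN graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.neighbors import NearestNeighbors

from tmeco.core_tables import ClusterCountTable


def shannon_entropy(counts) -> float:
    """Shannon entropy (nats) of a cluster count vector: ``-sum p_c ln p_c``."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("entropy of an all-zero count vector is undefined")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def bray_curtis(counts_i, counts_j) -> float:
    """Bray-Curtis dissimilarity between two aligned count vectors.

    0 for identical samples, 1 for disjoint supports.
    """
    x = np.asarray(counts_i, dtype=float)
    y = np.asarray(counts_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be aligned (zero-fill missing clusters)")
    tx, ty = x.sum(), y.sum()
    if tx <= 0 or ty <= 0:
        raise ValueError("both samples must have positive totals")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / (tx + ty))


@dataclass
class DissimilarityMatrix:
    """Averaged rarefied Bray-Curtis matrix with its rarefaction settings."""

    values: pd.DataFrame  # square, symmetric, zero diagonal
    n_cells: int
    iterations: int
    seed: int | None

    def pairs(self) -> pd.DataFrame:
        """Off-diagonal entries (i < j) in long form."""
        samples = list(self.values.index)
        rows = [
            {"sample_i": samples[i], "sample_j": samples[j], "d": self.values.iat[i, j]}
            for i, j in itertools.combinations(range(len(samples)), 2)
        ]
        return pd.DataFrame(rows)


def rarefied_dissimilarity(
    table: ClusterCountTable, n_cells: int = 400, iterations: int = 100, seed=0
) -> DissimilarityMatrix:
    """Average Bray-Curtis matrix over repeated rarefaction.

    Each iteration subsamples every retained sample to exactly ``n_cells``
    cells without replacement (multivariate hypergeometric draw from its
    cluster counts), computes all pairwise dissimilarities and averages over
    iterations. Samples with fewer than ``n_cells`` cells are dropped with a
    warning; fewer than two surviving samples is an error.
    """
    rng = np.random.default_rng(seed)
    totals = table.totals()
    keep = totals[totals >= n_cells].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below the rarefaction floor of "
            f"{n_cells} cells: {list(dropped)}",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ValueError("fewer than two samples survive the rarefaction floor")
    counts = table.counts.loc[keep].to_numpy(dtype=np.int64)
    n_samples = counts.shape[0]
    acc = np.zeros((n_samples, n_samples))
    for _ in range(iterations):
        sub = np.stack(
            [rng.multivariate_hypergeometric(row, n_cells) for row in counts]
        ).astype(float)
        mins = np.minimum(sub[:, None, :], sub[None, :, :]).sum(axis=2)
        acc += 1.0 - mins / n_cells  # totals are exactly n_cells each
    acc /= iterations
    np.fill_diagonal(acc, 0.0)
    values = pd.DataFrame(acc, index=keep, columns=keep)
    return DissimilarityMatrix(values=values, n_cells=n_cells, iterations=iterations, seed=seed)


def group_dissimilarity(
    dmat: DissimilarityMatrix,
    meta: pd.DataFrame,
    scheme: str = "intra_patient",
    patient_col: str = "patient_id",
    pair_filter: tuple[str, str, str] | None = None,
) -> pd.DataFrame:
    """Partition off-diagonal dissimilarities by patient scheme and site pair.

    ``scheme`` is ``"intra_patient"`` (both samples from one patient) or
    ``"inter_patient"``. ``pair_filter=(column, level_a, level_b)`` keeps only
    pairs where one sample carries ``level_a`` and the other ``level_b``
    (unordered; ``level_a == level_b`` selects homotypic pairs). Returns the
    qualifying pairs with their dissimilarities; an empty selection warns.
    """
    if scheme not in ("intra_patient", "inter_patient"):
        raise ValueError(f"unknown scheme {scheme!r}")
    pairs = dmat.pairs()
    missing = (set(pairs["sample_i"]) | set(pairs["sample_j"])) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing for samples: {sorted(missing)}")
    pi = meta.loc[pairs["sample_i"], patient_col].to_numpy()
    pj = meta.loc[pairs["sample_j"], patient_col].to_numpy()
    mask = (pi == pj) if scheme == "intra_patient" else (pi != pj)
    if pair_filter is not None:
        col, a, b = pair_filter
        vi = meta.loc[pairs["sample_i"], col].to_numpy()
        vj = meta.loc[pairs["sample_j"], col].to_numpy()
        mask &= ((vi == a) & (vj == b)) | ((vi == b) & (vj == a))
    out = pairs.loc[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("no sample pairs match the requested grouping", stacklevel=2)
    out.attrs["n_pairs"] = len(out)
    return out


def kde_enrichment(
    embedding: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    bandwidth: float | str = "scott",
    grid_size: int = 200,
    pad: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed relative-density field between two cell groups in an embedding.

    Gaussian-kernel densities of groups a and b are evaluated on a
    ``grid_size`` x ``grid_size`` grid over the padded bounding box of all
    cells, each normalized to unit mass on the grid, and subtracted
    (a minus b). Returns ``(grid_x, grid_y, field)``; the field sums to ~0.
    """
    for col in ("x", "y", group_col):
        if col not in embedding.columns:
            raise ValueError(f"embedding requires column {col!r}")
    xy = embedding[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("embedding coordinates must be finite")
    sel_a = embedding[group_col] == group_a
    sel_b = embedding[group_col] == group_b
    if not sel_a.any() or not sel_b.any():
        raise ValueError("both groups must be non-empty")
    span = xy.max(axis=0) - xy.min(axis=0)
    lo = xy.min(axis=0) - pad * span
    hi = xy.max(axis=0) + pad * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    mesh = np.stack(np.meshgrid(gx, gy, indexing="ij"))
    flat = mesh.reshape(2, -1)

    def _density(mask) -> np.ndarray:
        kde = gaussian_kde(xy[mask.to_numpy()].T, bw_method=bandwidth)
        d = kde(flat).reshape(grid_size, grid_size)
        return d / d.sum()

    return gx, gy, _density(sel_a) - _density(sel_b)


def knn_neighbours(embedding: pd.DataFrame, k: int = 20) -> np.ndarray:
    """Index array (n_cells, k) of Euclidean nearest neighbours, self excluded.

    Exact distance ties are broken by row order. ``k >= n_cells`` is an error;
    duplicate coordinates are allowed.
    """
    xy = embedding[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=min(n, k + 2)).fit(xy)
    dist, idx = nn.kneighbors(xy)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))
        row = [j for j in idx[i][order] if j != i]
        out[i] = row[:k]
    return out


def patient_specificity(
    neighbours: np.ndarray,
    patient_labels: pd.Series,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-cell log2 ratio of observed to expected same-patient neighbours.

    The expected fraction is each patient's global share of cells; a
    pseudocount (default ``1/k``) keeps cells with zero same-patient
    neighbours finite. A score of 0 means a perfectly mixed neighbourhood;
    positive scores mean patient-private phenotypes.
    """
    labels = pd.Series(patient_labels).reset_index(drop=True)
    if labels.isna().any():
        raise ValueError("patient labels contain missing values")
    n, k = neighbours.shape
    if len(labels) != n:
        raise ValueError("labels and neighbour sets disagree in length")
    delta = 1.0 / k if pseudocount is None else pseudocount
    lab = labels.to_numpy()
    same = (lab[neighbours] == lab[:, None]).mean(axis=1)
    expected = labels.map(labels.value_counts(normalize=True)).to_numpy()
    score = np.log2((same + delta) / (expected + delta))
    return pd.DataFrame(
        {
            "patient_id": lab,
            "observed_fraction": same,
            "expected_fraction": expected,
            "score": score,
        }
    )
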