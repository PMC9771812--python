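"""Synthetic cohorts with known ground truth for every pipeline input.

Each generator is a pure function of its specification and an explicit seed
(or :class:`numpy.random.Generator`): the same seed yields identical output.
The generators emulate only the statistical structure the downstream stages
consume — multinomial cluster counts under a logit-linear model, binomial
allele counts under allelic states, marked spatial point patterns around a
tumour–stroma interface, sparse gene counts with controlled expressing
fractions, signature-probability clouds, and toy segment/variant tables whose
records straddle every filter decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from shapely.geometry import Point, Polygon

from tmeco.core_tables import ClusterCountTable


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Cluster composition under a logit-linear model
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Sampling layout of a synthetic cohort.

    ``sites`` lists the anatomical sites sampled for each patient (one sample
    per entry); ``signatures`` assigns exactly one mutational-signature
    subtype per patient.
    """

    n_patients: int
    sites: Sequence[Sequence[str]]
    signatures: Sequence[str]
    n_clusters: int
    cells_per_sample: int = 2000

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_clusters < 1 or self.cells_per_sample < 1:
            raise ValueError("counts must be >= 1")
        if len(self.sites) != self.n_patients or len(self.signatures) != self.n_patients:
            raise ValueError("sites and signatures must have one entry per patient")


@dataclass
class EffectSpec:
    """Ground-truth effects on the per-cluster logits.

    Arrays are indexed (cluster, level); omitted terms default to zero.
    ``sigma`` is the standard deviation of per-logit Gaussian noise applied
    before the softmax.
    """

    baseline: np.ndarray  # (n_clusters,)
    site_levels: Sequence[str] = ()
    signature_levels: Sequence[str] = ()
    cluster_site: np.ndarray | None = None  # (n_clusters, n_sites)
    cluster_signature: np.ndarray | None = None  # (n_clusters, n_signatures)
    cluster_site_signature: np.ndarray | None = None  # (n_clusters, n_sites, n_sigs)
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("effects must be finite")

    @classmethod
    def null(cls, n_clusters: int, sites: Sequence[str], signatures: Sequence[str]) -> "EffectSpec":
        """All-zero effects for the given levels."""
        return cls(
            baseline=np.zeros(n_clusters),
            site_levels=tuple(sites),
            signature_levels=tuple(signatures),
            cluster_site=np.zeros((n_clusters, len(sites))),
            cluster_signature=np.zeros((n_clusters, len(signatures))),
        )


def simulate_composition(
    design: CohortDesign, effects: EffectSpec, seed=0
) -> tuple[ClusterCountTable, EffectSpec]:
    """Draw per-sample cluster counts from a softmax logit-linear model.

    For each sample, cluster logits are ``baseline + site effect + signature
    effect (+ three-way effect) (+ Normal(0, sigma^2) noise)``; probabilities
    are the softmax over clusters and counts are multinomial with the design's
    ``cells_per_sample`` total. When an effect is planted on a single cluster,
    the log odds of that cluster versus the rest differ between levels by
    exactly the planted coefficient, so a binomial-logit fit is unbiased for
    it. Returns the count table and the ground-truth effects.
    """
    rng = _rng(seed)
    site_idx = {s: i for i, s in enumerate(effects.site_levels)}
    sig_idx = {s: i for i, s in enumerate(effects.signature_levels)}
    rows, meta_rows, index = [], [], []
    for p in range(design.n_patients):
        patient = f"patient_{p:03d}"
        signature = design.signatures[p]
        for k, site in enumerate(design.sites[p]):
            eta = effects.baseline.copy()
            if effects.cluster_site is not None and site in site_idx:
                eta = eta + effects.cluster_site[:, site_idx[site]]
            if effects.cluster_signature is not None and signature in sig_idx:
                eta = eta + effects.cluster_signature[:, sig_idx[signature]]
            if (
                effects.cluster_site_signature is not None
                and site in site_idx
                and signature in sig_idx
            ):
                eta = eta + effects.cluster_site_signature[:, site_idx[site], sig_idx[signature]]
            if effects.sigma > 0:
                eta = eta + rng.normal(0.0, effects.sigma, size=eta.shape)
            eta = eta - eta.max()
            prob = np.exp(eta)
            prob /= prob.sum()
            rows.append(rng.multinomial(design.cells_per_sample, prob))
            meta_rows.append({"patient_id": patient, "site": site, "signature": signature})
            index.append(f"{patient}_{site}_{k}")
    counts = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(index, name="sample_id"),
        columns=pd.Index([f"cluster_{c}" for c in range(design.n_clusters)], name="cluster"),
    )
    meta = pd.DataFrame(meta_rows, index=counts.index)
    return ClusterCountTable(counts=counts, meta=meta), effects


# ---------------------------------------------------------------------------
# Per-cell allele counts under allelic states
# ---------------------------------------------------------------------------

ALLELIC_STATES = ("balanced", "imbalanced", "LOH")


@dataclass
class ArmStateSpec:
    """Clonal structure and sequencing model for allele-count simulation.

    ``clone_states`` maps clone name -> {arm -> state}; ``clone_fractions``
    must sum to 1. Total reads per (cell, SNP) are Poisson with mean
    ``depth_per_snp``; B-allele reads are binomial with success probability
    0.5 (balanced), ``imbalanced_baf`` (imbalanced) or the allele error rate
    ``epsilon`` (LOH).
    """

    clone_states: Mapping[str, Mapping[str, str]]
    clone_fractions: Mapping[str, float]
    n_cells: int = 500
    n_snps_per_arm: int = 30
    depth_per_snp: float = 3.0
    imbalanced_baf: float = 0.25
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not 0.15 <= self.imbalanced_baf < 0.35:
            raise ValueError("imbalanced_baf must lie in [0.15, 0.35)")
        if abs(sum(self.clone_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("clone fractions must sum to 1")
        for clone, states in self.clone_states.items():
            for arm, state in states.items():
                if state not in ALLELIC_STATES:
                    raise ValueError(f"unknown state {state!r} for clone {clone}, arm {arm}")

    @property
    def arms(self) -> list[str]:
        arms: list[str] = []
        for states in self.clone_states.values():
            for arm in states:
                if arm not in arms:
                    arms.append(arm)
        return arms


_STATE_BAF = {"balanced": 0.5}


def simulate_allele_counts(spec: ArmStateSpec, seed=0) -> tuple[AnnData, pd.DataFrame]:
    """Simulate a cells x SNPs allele-count matrix with per-cell truth states.

    Returns an :class:`~anndata.AnnData` with sparse ``ref``/``alt`` layers
    (X holds total counts) and SNP metadata (``chrom``, ``pos``, ``arm``) in
    ``.var``, plus a long truth table (cell_id, arm, clone, state). The
    simulated alt allele is the B allele (minor by construction); cells with
    zero reads on an arm are present with zero counts.
    """
    rng = _rng(seed)
    clones = list(spec.clone_states)
    fractions = np.array([spec.clone_fractions[c] for c in clones])
    assignment = rng.choice(len(clones), size=spec.n_cells, p=fractions)
    arms = spec.arms
    snp_arm = np.repeat(arms, spec.n_snps_per_arm)
    n_snps = len(snp_arm)
    baf_by_state = {
        "balanced": 0.5,
        "imbalanced": spec.imbalanced_baf,
        "LOH": spec.epsilon,
    }
    total = rng.poisson(spec.depth_per_snp, size=(spec.n_cells, n_snps))
    q = np.empty((spec.n_cells, n_snps))
    truth_rows = []
    for i, clone_i in enumerate(assignment):
        clone = clones[clone_i]
        for arm in arms:
            state = spec.clone_states[clone].get(arm, "balanced")
            q[i, snp_arm == arm] = baf_by_state[state]
            truth_rows.append(
                {"cell_id": f"cell_{i:04d}", "arm": arm, "clone": clone, "state": state}
            )
    alt = rng.binomial(total, q)
    ref = total - alt
    var = pd.DataFrame(
        {
            "chrom": ["6" if a.startswith("6") else a.rstrip("pq") for a in snp_arm],
            "pos": np.arange(1, n_snps + 1) * 1000,
            "arm": snp_arm,
        },
        index=pd.Index([f"snp_{j:04d}" for j in range(n_snps)], name="snp_id"),
    )
    obs = pd.DataFrame(
        {"clone": [clones[c] for c in assignment]},
        index=pd.Index([f"cell_{i:04d}" for i in range(spec.n_cells)], name="cell_id"),
    )
    adata = AnnData(
        X=sparse.csr_matrix(total),
        obs=obs,
        var=var,
        layers={"ref": sparse.csr_matrix(ref), "alt": sparse.csr_matrix(alt)},
    )
    return adata, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Marked spatial point patterns with a tumour-stroma interface
# ---------------------------------------------------------------------------


@dataclass
class FovSpec:
    """One field of view: frame, interface geometry and phenotype intensities.

    ``tumour`` is a polygon (µm) whose boundary is the tumour–stroma
    interface; cells inside it are in the tumour region. ``intensity`` maps
    phenotype -> function of signed boundary distance (positive on the tumour
    side) giving a relative point-process intensity; ``n_cells`` maps
    phenotype -> expected cell count.
    """

    width: float = 600.0
    height: float = 400.0
    tumour: Polygon | None = None
    intensity: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    n_cells: Mapping[str, int] = field(default_factory=dict)
    fov_id: str = "fov_0"

    def __post_init__(self) -> None:
        if self.tumour is None:
            # default: right half of the frame is tumour; interface is vertical
            self.tumour = Polygon(
                [
                    (self.width / 2, -1e6),
                    (self.width + 1e6, -1e6),
                    (self.width + 1e6, self.height + 1e6),
                    (self.width / 2, self.height + 1e6),
                ]
            )
        if self.tumour.boundary.length == 0:
            raise ValueError("degenerate tumour boundary (zero length)")


def signed_boundary_distance(x, y, tumour: Polygon) -> np.ndarray:
    """Signed Euclidean distance (µm) to the tumour boundary; + inside tumour."""
    boundary = tumour.boundary
    out = np.empty(len(np.atleast_1d(x)), dtype=float)
    for i, (xi, yi) in enumerate(zip(np.atleast_1d(x), np.atleast_1d(y))):
        p = Point(float(xi), float(yi))
        d = p.distance(boundary)
        out[i] = d if tumour.covers(p) else -d
    return out


def simulate_spatial_fov(spec: FovSpec, seed=0) -> pd.DataFrame:
    """Sample cells from inhomogeneous point processes tied to the interface.

    Each phenotype's intensity depends only on signed boundary distance;
    points are drawn by thinning a uniform proposal over the frame. Returns a
    table (cell_id, fov_id, x, y in µm, phenotype, region, signed_distance).
    """
    rng = _rng(seed)
    rows = []
    for phenotype, n in spec.n_cells.items():
        profile = spec.intensity.get(phenotype)
        accepted = 0
        guard = 0
        pts: list[tuple[float, float, float]] = []
        while accepted < n:
            guard += 1
            if guard > 2000:
                raise RuntimeError(f"thinning failed to place cells for {phenotype!r}")
            m = max(4 * (n - accepted), 64)
            xs = rng.uniform(0, spec.width, m)
            ys = rng.uniform(0, spec.height, m)
            d = signed_boundary_distance(xs, ys, spec.tumour)
            if profile is None:
                keep = np.ones(m, dtype=bool)
            else:
                w = np.asarray(profile(d), dtype=float)
                if (w < 0).any():
                    raise ValueError("intensity profile must be non-negative")
                top = w.max()
                keep = rng.uniform(0, 1, m) < (w / top if top > 0 else 0)
            for xi, yi, di in zip(xs[keep], ys[keep], d[keep]):
                if accepted >= n:
                    break
                pts.append((xi, yi, di))
                accepted += 1
        for xi, yi, di in pts:
            rows.append(
                {
                    "fov_id": spec.fov_id,
                    "x": xi,
                    "y": yi,
                    "phenotype": phenotype,
                    "region": "tumour" if di >= 0 else "stroma",
                    "signed_distance": di,
                }
            )
    cells = pd.DataFrame(rows)
    cells.insert(0, "cell_id", [f"{spec.fov_id}_cell_{i:05d}" for i in range(len(cells))])
    return cells


def attach_marker_intensities(
    cells: pd.DataFrame,
    phenotype_markers: Mapping[str, Sequence[str]],
    markers: Sequence[str],
    positive_level: float = 10.0,
    negative_level: float = 1.0,
    noise_sd: float = 0.5,
    seed=0,
) -> pd.DataFrame:
    """Add mean marker-intensity columns consistent with phenotype labels.

    Markers listed for a cell's phenotype receive intensities around
    ``positive_level``; all others around ``negative_level`` (clipped at 0),
    emulating mpIF mean pixel intensities for gating tests.
    """
    rng = _rng(seed)
    out = cells.copy()
    for marker in markers:
        pos = out["phenotype"].map(lambda ph: marker in phenotype_markers.get(ph, ()))
        level = np.where(pos, positive_level, negative_level)
        out[marker] = np.clip(level + rng.normal(0, noise_sd, len(out)), 0, None)
    return out


# ---------------------------------------------------------------------------
# Sparse expression counts with controlled expressing fractions
# ---------------------------------------------------------------------------


def simulate_expression_counts(
    n_patients: int,
    clusters: Sequence[str],
    genes: Sequence[str],
    expressing_fractions,
    cells_per_group: int = 200,
    seed=0,
) -> tuple[sparse.csr_matrix, pd.DataFrame, list[str]]:
    """Simulate sparse counts where each gene's expressing fraction is set.

    ``expressing_fractions`` is either ``{gene: fraction}`` or a callable
    ``f(patient, cluster, gene) -> fraction``. Cells chosen to express a gene
    get counts ``>= 1`` (1 + Poisson). Returns (CSR matrix cells x genes,
    cell metadata with patient/cluster, gene list).
    """
    rng = _rng(seed)
    if callable(expressing_fractions):
        frac_fn = expressing_fractions
    else:
        table = dict(expressing_fractions)
        frac_fn = lambda p, c, g: table.get(g, 0.0)  # noqa: E731
    meta_rows = []
    blocks = []
    for p in range(n_patients):
        patient = f"patient_{p:03d}"
        for cluster in clusters:
            block = np.zeros((cells_per_group, len(genes)), dtype=np.int64)
            for j, gene in enumerate(genes):
                f = float(frac_fn(patient, cluster, gene))
                if not 0 <= f <= 1:
                    raise ValueError("expressing fractions must lie in [0, 1]")
                on = rng.uniform(0, 1, cells_per_group) < f
                block[on, j] = 1 + rng.poisson(1.0, int(on.sum()))
            blocks.append(block)
            meta_rows.extend(
                {"patient_id": patient, "cluster": cluster} for _ in range(cells_per_group)
            )
    matrix = sparse.csr_matrix(np.vstack(blocks))
    meta = pd.DataFrame(meta_rows)
    meta.insert(0, "cell_id", [f"cell_{i:06d}" for i in range(len(meta))])
    return matrix, meta, list(genes)


# ---------------------------------------------------------------------------
# Signature-probability clouds
# ---------------------------------------------------------------------------


def simulate_signature_profiles(
    n_per_stratum: int,
    centroids: Mapping[str, Sequence[float]],
    spread: float = 0.02,
    seed=0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian clouds around stratum centroids in signature-probability space.

    Points are clipped to be non-negative and renormalized onto the simplex.
    Returns (profiles DataFrame, labels Series) sharing a sample index.
    """
    rng = _rng(seed)
    dim = len(next(iter(centroids.values())))
    profiles, labels = [], []
    for label, centre in centroids.items():
        pts = rng.normal(np.asarray(centre, dtype=float), spread, size=(n_per_stratum, dim))
        pts = np.clip(pts, 0, None)
        sums = pts.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        profiles.append(pts / sums)
        labels.extend([label] * n_per_stratum)
    frame = pd.DataFrame(
        np.vstack(profiles),
        columns=[f"sig_{j}" for j in range(dim)],
        index=pd.Index([f"sample_{i:04d}" for i in range(n_per_stratum * len(centroids))]),
    )
    return frame, pd.Series(labels, index=frame.index, name="stratum")


# ---------------------------------------------------------------------------
# Toy genomic fixtures straddling every filter boundary
# ---------------------------------------------------------------------------


def simulate_segments(mode: str = "wgs") -> pd.DataFrame:
    """Deterministic segment tables with one record per decision boundary.

    ``mode='wgs'`` targets the homozygous-deletion rule (>= 10 kb, mean copy
    number < 0.5); ``mode='panel'`` targets the panel focal-event rules
    (< 10 Mb, <= 10 genes; amplification cn > 8; deletion cn == 0).
    """
    if mode == "wgs":
        return pd.DataFrame(
            [
                # chrom, start, end (1-based inclusive), copy_number
                ("1", 1_000_001, 1_015_000, 0.3),  # 15 kb, deleted -> call
                ("1", 2_000_001, 2_008_000, 0.2),  # 8 kb, too short -> no call
                ("1", 3_000_001, 3_010_000, 0.5),  # cn exactly 0.5 -> no call (strict <)
                ("1", 4_000_001, 4_010_000, 0.49),  # exactly 10 kb, cn < 0.5 -> call
                ("2", 5_000_001, 5_500_000, 2.0),  # normal -> no call
            ],
            columns=["chrom", "start", "end", "copy_number"],
        )
    if mode == "panel":
        return pd.DataFrame(
            [
                # chrom, start, end, copy_number, n_genes
                ("1", 1, 5_000_000, 9, 8),  # eligible, cn 9 -> amplification
                ("1", 1, 5_000_000, 9, 11),  # 11 genes -> none
                ("1", 1, 12_000_000, 9, 8),  # 12 Mb -> none (size)
                ("2", 1, 2_000_000, 0, 3),  # eligible, cn 0 -> homozygous deletion
                ("2", 1, 2_000_000, 8, 3),  # cn exactly 8 -> none (strict >)
                ("2", 1, 2_000_000, 1, 3),  # cn 1 -> none
            ],
            columns=["chrom", "start", "end", "copy_number", "n_genes"],
        )
    raise ValueError(f"unknown mode {mode!r}")


def simulate_variants() -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Toy SNV table plus blacklist and known-variant set for the SNV filter.

    Returns (variants, blacklist BED-like table, known set). Records straddle
    each rule: caller intersection, probability >= 0.9, blacklist overlap and
    known-variant removal; each boundary fixture appears exactly once.
    """
    variants = pd.DataFrame(
        [
            # chrom, pos (1-based), ref, alt, callers, probability
            ("1", 100, "A", "T", "mutationseq;strelka", 0.95),  # kept
            ("1", 200, "C", "G", "strelka", 0.99),  # single caller -> removed
            ("1", 300, "G", "A", "mutationseq;strelka", 0.89),  # prob < 0.9 -> removed
            ("1", 400, "T", "C", "mutationseq;strelka", 0.90),  # boundary prob -> kept
            ("1", 1005, "A", "G", "mutationseq;strelka", 0.99),  # in blacklist -> removed
            ("1", 2000, "C", "T", "mutationseq;strelka", 0.99),  # known variant -> removed
            ("2", 100, "G", "T", "mutationseq;strelka", 0.99),  # kept
        ],
        columns=["chrom", "pos", "ref", "alt", "callers", "probability"],
    )
    blacklist = pd.DataFrame(
        [("1", 1000, 1100)], columns=["chrom", "start", "end"]
    )  # BED: 0-based half-open
    known = {("1", 2000, "C", "T")}
    return variants, blacklist, known


def simulate_breakpoints() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy breakpoint table plus blacklist for the three-step SV filter."""
    bps = pd.DataFrame(
        [
            # id, type, chrom1, pos1, chrom2, pos2, break_distance, size,
            # tumour_reads, normal_reads, callers
            ("bp1", "deletion", "1", 10_000, "1", 15_000, 200, 5000, 5, 0, "lumpy;destruct"),  # kept
            ("bp2", "deletion", "1", 20_000, "1", 20_800, 200, 800, 9, 0, "lumpy;destruct"),  # <1 kb del -> removed
            ("bp3", "duplication", "1", 30_000, "1", 30_800, 200, 800, 9, 0, "lumpy;destruct"),  # small dup -> kept
            ("bp4", "inversion", "2", 10_000, "2", 50_000, 30, 40_000, 20, 0, "lumpy;destruct"),  # break distance <= 30 -> removed
            ("bp5", "translocation", "2", 10_000, "3", 50_000, 200, 0, 4, 0, "lumpy;destruct"),  # <5 tumour reads -> removed
            ("bp6", "inversion", "2", 60_000, "2", 90_000, 200, 30_000, 10, 1, "lumpy;destruct"),  # normal support -> removed
            ("bp7", "duplication", "3", 10_000, "3", 90_000, 200, 80_000, 12, 0, "destruct"),  # single caller -> removed
            ("bp8", "inversion", "4", 1_050, "4", 90_000, 200, 88_950, 12, 0, "lumpy;destruct"),  # locus in blacklist -> removed
            ("bp9", "inversion", "5", 10_000, "5", 90_000, 50, 80_000, 6, 0, "lumpy;destruct"),  # small distance + few reads -> removed (step 3)
            ("bp10", "foldback", "5", 100_000, "5", 140_000, 500, 40_000, 15, 0, "lumpy;destruct"),  # kept
        ],
        columns=[
            "breakpoint_id",
            "type",
            "chrom1",
            "pos1",
            "chrom2",
            "pos2",
            "break_distance",
            "size",
            "tumour_reads",
            "normal_reads",
            "callers",
        ],
    )
    blacklist = pd.DataFrame([("4", 1000, 1100)], columns=["chrom", "start", "end"])
    return bps, blacklist
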