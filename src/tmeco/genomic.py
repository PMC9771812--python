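"""Deterministic genomic rules: signature strata, focal CNAs, variant filters.

Implements a k-nearest-neighbour majority-vote classifier over mutational
signature probability vectors (k = 30 neighbours, m = 25 votes required,
otherwise Undetermined), focal amplification / homozygous deletion calls for
whole-genome bins and panel segments, and high-confidence SNV and breakpoint
filters (caller intersection, probability, blacklist and support-read rules).
All filters are pure predicates: output is a subset of input, order-invariant
and idempotent.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

UNDETERMINED = "Undetermined"


# ---------------------------------------------------------------------------
# kNN mutational-signature strata
# ---------------------------------------------------------------------------


def knn_signature_assign(
    test: pd.DataFrame,
    reference: pd.DataFrame,
    reference_labels: pd.Series,
    k: int = 30,
    m: int = 25,
) -> pd.Series:
    """Assign signature strata by majority vote of Euclidean nearest references.

    Each test profile takes the modal label among its ``k`` nearest reference
    profiles iff that label holds at least ``m`` votes; otherwise it is
    ``Undetermined``. Distance ties are broken by reference row order; a vote
    tie at or above ``m`` (only possible when ``m <= k/2``) resolves to the
    alphabetically first label.
    """
    if k > len(reference):
        raise ValueError(f"k={k} exceeds the reference size ({len(reference)})")
    ref = reference.to_numpy(dtype=float)
    labels = reference_labels.to_numpy()
    out = []
    for _, row in test.iterrows():
        d = np.linalg.norm(ref - row.to_numpy(dtype=float), axis=1)
        nearest = np.lexsort((np.arange(len(d)), d))[:k]
        votes = pd.Series(labels[nearest]).value_counts()
        top = votes.index[votes == votes.max()].sort_values()[0]
        out.append(top if votes.max() >= m else UNDETERMINED)
    return pd.Series(out, index=test.index, name="stratum")


# ---------------------------------------------------------------------------
# Focal amplifications and homozygous deletions
# ---------------------------------------------------------------------------


def call_focal_amplifications_wgs(
    bins: pd.DataFrame, ploidy: float, top_fraction: float = 0.02
) -> pd.Series:
    """Flag bins that are both extreme and strongly amplified over ploidy.

    A bin is flagged iff its copy number lies in the top ``top_fraction`` of
    the genome-wide distribution AND ``log2(copy_number / ploidy) > 1``.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    cn = bins["copy_number"].to_numpy(dtype=float)
    cutoff = np.quantile(cn, 1.0 - top_fraction)
    with np.errstate(divide="ignore"):
        log_change = np.log2(np.where(cn > 0, cn, np.nan) / ploidy)
    return pd.Series((cn >= cutoff) & (log_change > 1.0), index=bins.index, name="focal_amp")


def call_homozygous_deletions_wgs(
    segments: pd.DataFrame, min_length: int = 10_000, max_copy: float = 0.5
) -> pd.Series:
    """Flag segments >= 10 kb with mean copy number strictly below 0.5.

    Lengths use 1-based inclusive coordinates (``end - start + 1``).
    """
    length = segments["end"] - segments["start"] + 1
    return pd.Series(
        (length >= min_length) & (segments["copy_number"] < max_copy),
        index=segments.index,
        name="homozygous_deletion",
    )


def call_panel_focal_events(
    segments: pd.DataFrame,
    max_length: int = 10_000_000,
    max_genes: int = 10,
    amp_copy: float = 8,
) -> pd.Series:
    """Classify panel segments as amplification / homozygous_deletion / none.

    Only segments shorter than 10 Mb with at most 10 genes are eligible
    (suppressing arm-level events); eligible segments with total copy number
    strictly above 8 are high-level amplifications and those with total copy
    number 0 are homozygous deletions.
    """
    length = segments["end"] - segments["start"] + 1
    eligible = (length < max_length) & (segments["n_genes"] <= max_genes)
    call = np.where(
        eligible & (segments["copy_number"] > amp_copy),
        "amplification",
        np.where(eligible & (segments["copy_number"] == 0), "homozygous_deletion", "none"),
    )
    return pd.Series(call, index=segments.index, name="event")


# ---------------------------------------------------------------------------
# Blacklist interval handling (BED, 0-based half-open)
# ---------------------------------------------------------------------------


def build_blacklist(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    """Interval trees per chromosome from a BED-like table (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for _, row in bed.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if end <= start:
            raise ValueError(f"malformed interval: {row['chrom']}:{start}-{end}")
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(start, end)
    return trees


def _in_blacklist(trees: Mapping[str, IntervalTree], chrom: str, pos_1based: int) -> bool:
    # 1-based position pos maps to the 0-based coordinate pos - 1
    tree = trees.get(str(chrom))
    return bool(tree is not None and tree.overlaps_point(int(pos_1based) - 1))


def _callers(value) -> set[str]:
    if isinstance(value, str):
        return {c for c in value.replace(",", ";").split(";") if c}
    return set(value)


# ---------------------------------------------------------------------------
# High-confidence SNV and breakpoint filters
# ---------------------------------------------------------------------------


def filter_snvs(
    variants: pd.DataFrame,
    blacklist: pd.DataFrame,
    known: Iterable[tuple] = (),
    required_callers: tuple[str, str] = ("mutationseq", "strelka"),
    min_probability: float = 0.9,
) -> pd.DataFrame:
    """High-confidence SNVs: caller intersection, probability and region filters.

    A variant is kept iff it was called by both required callers, its
    mutationSeq probability is >= ``min_probability``, its (1-based) position
    overlaps no blacklist interval and it is not in the known-variant set
    (keys ``(chrom, pos, ref, alt)``).
    """
    trees = build_blacklist(blacklist)
    known_set = set(known)
    need = set(required_callers)

    def _keep(row) -> bool:
        return (
            need <= _callers(row["callers"])
            and row["probability"] >= min_probability
            and not _in_blacklist(trees, row["chrom"], row["pos"])
            and (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]) not in known_set
        )

    keep = variants.apply(_keep, axis=1) if len(variants) else pd.Series(dtype=bool)
    return variants.loc[keep].copy()


def filter_breakpoints(
    breakpoints: pd.DataFrame,
    blacklist: pd.DataFrame,
    required_callers: tuple[str, str] = ("lumpy", "destruct"),
    min_break_distance: int = 30,
    min_deletion_size: int = 1_000,
    min_tumour_reads: int = 5,
    step3_max_distance: int = 100,
    step3_min_reads: int = 10,
) -> pd.DataFrame:
    """Three-step high-confidence breakpoint filter.

    Keep a breakpoint iff it was predicted by both callers; its break
    distance exceeds 30 bp; it is not a deletion smaller than 1,000 bp; it
    has at least five tumour supporting reads and none in the matched
    normal; neither locus overlaps the blacklist; and it does not combine a
    small break distance with few supporting reads (default: distance
    < ``step3_max_distance`` and tumour reads < ``step3_min_reads`` — the
    original rule is unquantified, so these are explicit parameters).
    """
    trees = build_blacklist(blacklist)
    need = set(required_callers)

    def _keep(row) -> bool:
        if not need <= _callers(row["callers"]):
            return False
        if row["break_distance"] <= min_break_distance:
            return False
        if row["type"] == "deletion" and row["size"] < min_deletion_size:
            return False
        if row["tumour_reads"] < min_tumour_reads or row["normal_reads"] != 0:
            return False
        if _in_blacklist(trees, row["chrom1"], row["pos1"]) or _in_blacklist(
            trees, row["chrom2"], row["pos2"]
        ):
            return False
        if row["break_distance"] < step3_max_distance and row["tumour_reads"] < step3_min_reads:
            return False
        return True

    keep = breakpoints.apply(_keep, axis=1) if len(breakpoints) else pd.Series(dtype=bool)
    return breakpoints.loc[keep].copy()
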