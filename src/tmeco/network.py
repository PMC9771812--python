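"""Ligand-receptor co-expression networks between cell clusters.

For the PD-1 axis, a sender cluster (cancer or myeloid) and receiver cluster
(T cell) are linked for a patient when a ligand (*CD274* or *PDCD1LG2*) is
expressed in more than 10% of the sender cluster's cells and the receptor
(*PDCD1*) in more than 10% of the receiver cluster's cells; within a patient
group, an edge is drawn when the pair co-expresses in at least 50% of the
group's patients. All thresholds are explicit parameters.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

DEFAULT_LIGANDS = ("CD274", "PDCD1LG2")
DEFAULT_RECEPTOR = "PDCD1"


def expressing_fraction(
    counts: sparse.spmatrix,
    cell_meta: pd.DataFrame,
    genes: Sequence[str],
    gene: str,
) -> pd.DataFrame:
    """Fraction of cells with count > 0 for ``gene``, per (patient, cluster).

    ``counts`` is cells x genes; ``cell_meta`` carries ``patient_id`` and
    ``cluster`` aligned to its rows. Returns a table with columns
    ``patient_id``, ``cluster``, ``fraction`` and ``n_cells``.
    """
    genes = list(genes)
    if gene not in genes:
        raise KeyError(f"gene {gene!r} not present in the feature set")
    col = np.asarray(sparse.csc_matrix(counts)[:, genes.index(gene)].todense()).ravel()
    expressed = col > 0
    frame = cell_meta[["patient_id", "cluster"]].copy()
    frame["expressed"] = expressed
    out = (
        frame.groupby(["patient_id", "cluster"], observed=True)["expressed"]
        .agg(fraction="mean", n_cells="size")
        .reset_index()
    )
    out["gene"] = gene
    return out


def patient_coexpression_flag(
    sender_summary: pd.DataFrame,
    receiver_summary: pd.DataFrame,
    ligands: Sequence[str] = DEFAULT_LIGANDS,
    receptor: str = DEFAULT_RECEPTOR,
    min_fraction: float = 0.10,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-(patient, sender, receiver) ligand-receptor co-expression flags.

    A pair is flagged for a patient iff any ligand's expressing fraction in
    the sender cluster and the receptor's fraction in the receiver cluster
    both strictly exceed ``min_fraction``. A cluster counts as observed for a
    patient only with at least ``min_cells`` cells; rows are emitted only for
    patients where both clusters are observed, so absent clusters are not
    counted as non-co-expressing.
    """
    send = sender_summary[
        (sender_summary["gene"].isin(ligands)) & (sender_summary["n_cells"] >= min_cells)
    ]
    recv = receiver_summary[
        (receiver_summary["gene"] == receptor) & (receiver_summary["n_cells"] >= min_cells)
    ]
    send_ok = (
        send.assign(ok=send["fraction"] > min_fraction)
        .groupby(["patient_id", "cluster"], observed=True)["ok"]
        .any()
    )
    recv_ok = recv.set_index(["patient_id", "cluster"])["fraction"] > min_fraction
    rows = []
    for (patient, sender), s_ok in send_ok.items():
        for (p2, receiver), r_ok in recv_ok.items():
            if p2 != patient:
                continue
            rows.append(
                {
                    "patient_id": patient,
                    "sender": sender,
                    "receiver": receiver,
                    "flag": bool(s_ok and r_ok),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "sender", "receiver", "flag"])


def build_network(
    flags: pd.DataFrame,
    patient_groups: Mapping[str, str],
    min_patient_fraction: float = 0.50,
    denominator: str = "observed",
) -> pd.DataFrame:
    """Edge list per patient group from co-expression flags.

    An edge (sender, receiver) is included for a group when the pair is
    flagged in at least ``min_patient_fraction`` of the denominator patients:
    with ``denominator='observed'`` (default), patients contributing a flag
    row for the pair; with ``'group'``, all patients of the group. Returns
    columns group, sender, receiver, support fraction, n_flagged and
    n_patients; groups without qualifying pairs yield no rows (empty groups
    warn).
    """
    if denominator not in ("observed", "group"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    flags = flags.copy()
    unassigned = set(flags["patient_id"]) - set(patient_groups)
    if unassigned:
        raise ValueError(f"patients without a group: {sorted(unassigned)}")
    flags["group"] = flags["patient_id"].map(patient_groups)
    edges = []
    for group in sorted(set(patient_groups.values())):
        sub = flags[flags["group"] == group]
        group_size = sum(1 for g in patient_groups.values() if g == group)
        if sub.empty:
            warnings.warn(f"patient group {group!r} has no co-expression rows", stacklevel=2)
            continue
        grouped = sub.groupby(["sender", "receiver"], observed=True)["flag"].agg(["sum", "size"])
        for (sender, receiver), row in grouped.iterrows():
            n_flagged = int(row["sum"])
            denom = int(row["size"]) if denominator == "observed" else group_size
            support = n_flagged / denom if denom else 0.0
            if support >= min_patient_fraction and n_flagged > 0:
                edges.append(
                    {
                        "group": group,
                        "sender": sender,
                        "receiver": receiver,
                        "support": support,
                        "n_flagged": n_flagged,
                        "n_patients": denom,
                    }
                )
    return pd.DataFrame(
        edges, columns=["group", "sender", "receiver", "support", "n_flagged", "n_patients"]
    )
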