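"""Per-substate contact statistics and hotspot cross-referencing.

Within each substate (cluster of snapshots) every contact has a
relative frequency F_c(XY) — the proportion of the cluster's snapshots
showing it.  Two residue-level summaries follow:

* max variance: var(X) = max over partners Y of the population variance
  of F_c(XY) across clusters — high values mark residues whose contacts
  differ between substates;
* recurrence index: min over clusters of (max over partners of F_c(XY))
  — high values mark residues engaged at the interface in *every*
  substate, insensitive to cluster-size imbalance.

Experimental hotspots (single-point mutations with ΔΔG below a
threshold) can be joined onto these scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterLabels
from .contacts import Contact, ContactSet, ResidueRef

__all__ = [
    "ContactFrequencyTable",
    "MutationTable",
    "contact_frequencies",
    "contact_variance",
    "residue_max_variance",
    "recurrence_index",
    "hotspot_crossref",
]


@dataclass
class ContactFrequencyTable:
    """Relative frequency of each contact in each cluster."""

    frequencies: dict[Contact, np.ndarray]  # contact -> per-cluster F_c in [0,1]
    n_clusters: int
    cluster_sizes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def contacts_of(self, residue: ResidueRef) -> list[Contact]:
        return [c for c in self.frequencies if residue in c]

    def residues(self) -> list[ResidueRef]:
        seen: dict[ResidueRef, None] = {}
        for a, b in self.frequencies:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (r1, r2), freqs in self.frequencies.items():
            for c, f in enumerate(freqs, start=1):
                rows.append(
                    {
                        "chain1": r1[0], "resid1": r1[1],
                        "chain2": r2[0], "resid2": r2[1],
                        "cluster": c, "frequency": f,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class MutationTable:
    """Single-point mutation ΔΔG records (SKEMPI-style)."""

    records: pd.DataFrame  # columns: chain, resid, mutation, ddg_kcal_mol

    @classmethod
    def from_csv(cls, path) -> "MutationTable":
        df = pd.read_csv(path)
        required = {"chain", "resid", "mutation", "ddg_kcal_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"mutation table missing columns {sorted(missing)}")
        multi = df["mutation"].astype(str).str.contains(",")
        return cls(records=df[~multi].reset_index(drop=True))


def contact_frequencies(
    series: list[ContactSet], labels: ClusterLabels
) -> ContactFrequencyTable:
    """F_c(XY) per contact per cluster; unseen combinations are 0."""
    if len(series) != len(labels.labels):
        raise ValueError("labels do not align with the contact series")
    k = labels.n_clusters
    sizes = np.bincount(labels.labels, minlength=k + 1)[1:]
    if (sizes == 0).any():
        raise ValueError("empty cluster in labels")
    counts: dict[Contact, np.ndarray] = {}
    for cs, lab in zip(series, labels.labels):
        for contact in cs.contacts:
            counts.setdefault(contact, np.zeros(k))[lab - 1] += 1
    freqs = {c: v / sizes for c, v in counts.items()}
    return ContactFrequencyTable(
        frequencies=freqs, n_clusters=k, cluster_sizes=sizes
    )


def contact_variance(table: ContactFrequencyTable) -> dict[Contact, float]:
    """Population variance of the per-cluster frequencies of each contact.

    The divide-by-N_c variance keeps the upper bound at 0.25 for
    frequencies in [0, 1], appropriate for the 2–4 cluster regime.
    """
    if table.n_clusters < 2:
        raise ValueError("contact variance needs at least 2 clusters")
    return {c: float(np.var(f)) for c, f in table.frequencies.items()}


def residue_max_variance(
    variances: dict[Contact, float]
) -> dict[ResidueRef, float]:
    """var(X): maximum contact variance over the partners of each residue."""
    out: dict[ResidueRef, float] = {}
    for (r1, r2), v in variances.items():
        for r in (r1, r2):
            out[r] = max(out.get(r, 0.0), v)
    return out


def recurrence_index(table: ContactFrequencyTable) -> dict[ResidueRef, float]:
    """min over clusters of max over partners of F_c(XY), per residue.

    A residue with no contact observed in some cluster has an empty
    inner maximum there, hence recurrence 0.
    """
    best: dict[ResidueRef, np.ndarray] = {}
    for (r1, r2), freqs in table.frequencies.items():
        for r in (r1, r2):
            cur = best.setdefault(r, np.zeros(table.n_clusters))
            np.maximum(cur, freqs, out=cur)
    return {r: float(v.min()) for r, v in best.items()}


def hotspot_crossref(
    recurrence: dict[ResidueRef, float],
    max_variance: dict[ResidueRef, float],
    mutations: MutationTable,
    threshold: float = -2.0,
    flip_sign: bool = False,
) -> tuple[pd.DataFrame, list[ResidueRef]]:
    """Join residue scores with experimental hotspot flags.

    A residue is a hotspot when any single mutation at it has
    ΔΔG < ``threshold`` kcal/mol (the inequality as printed in the
    source convention; ``flip_sign=True`` negates ΔΔG first for tables
    using the opposite destabilising-positive convention).  Mutations at
    residues absent from the scores are returned as a warning list.
    """
    ddg = mutations.records["ddg_kcal_mol"].astype(float)
    if flip_sign:
        ddg = -ddg
    hot: set[ResidueRef] = set()
    unmatched: list[ResidueRef] = []
    for (_, row), g in zip(mutations.records.iterrows(), ddg):
        ref = (str(row["chain"]), int(row["resid"]))
        if ref not in recurrence:
            if ref not in unmatched:
                unmatched.append(ref)
            continue
        if g < threshold:
            hot.add(ref)
    rows = [
        {
            "chain": r[0],
            "resid": r[1],
            "recurrence_index": recurrence[r],
            "max_variance": max_variance.get(r, 0.0),
            "hotspot": r in hot,
        }
        for r in sorted(recurrence, key=lambda x: (x[0], x[1]))
    ]
    return pd.DataFrame(rows), unmatched
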