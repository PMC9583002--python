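"""Structural-water analyses: shells, released waters, bridges.

All distances are between water oxygens and protein heavy atoms.  The
first hydration shell holds waters with minimal distance d_m < 3.4 Å,
the second 3.4 ≤ d_m < 5.0 Å (half-open bins, each water in at most one
shell).  Released waters upon complexation are estimated as
mean_t N(free A) + mean_t N(free B) − mean_t N(complex) for the chosen
shell.  Interfacial waters sit within 4 Å of heavy atoms of both chains
simultaneously; a water bridging a residue of each chain within that
cutoff defines a water-mediated contact for the pair (counted once per
snapshot regardless of how many waters bridge it, and the bridging
water identity is free to change between snapshots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .clustering import ClusterLabels
from .contacts import ResidueRef
from .geometry import InterfaceRegions
from .snapshots import Snapshot, SnapshotSeries

__all__ = [
    "ShellCounts",
    "FIRST_SHELL_CUTOFF",
    "SECOND_SHELL_CUTOFF",
    "INTERFACIAL_CUTOFF",
    "water_min_distances",
    "shell_counts",
    "released_waters",
    "interfacial_waters",
    "water_mediated_contacts",
    "residue_water_contact_counts",
]

FIRST_SHELL_CUTOFF = 3.4  # Å
SECOND_SHELL_CUTOFF = 5.0  # Å
INTERFACIAL_CUTOFF = 4.0  # Å


@dataclass
class ShellCounts:
    time: float
    n_first_shell: int
    n_second_shell: int


def water_min_distances(
    snapshot: Snapshot, scope: list[str] | None = None
) -> np.ndarray:
    """d_m per water: minimal distance to any heavy atom of the scope chains."""
    if snapshot.n_waters == 0:
        return np.empty(0)
    if scope is None:
        mask = np.ones(snapshot.n_atoms, dtype=bool)
    else:
        mask = np.isin(snapshot.chain_ids, list(scope))
    if not mask.any():
        raise ValueError(f"no atoms in scope {scope}")
    tree = cKDTree(snapshot.xyz[mask])
    d, _ = tree.query(snapshot.water_xyz, k=1)
    return d


def shell_counts(
    snapshot: Snapshot,
    scope: list[str] | None = None,
    first_cutoff: float = FIRST_SHELL_CUTOFF,
    second_cutoff: float = SECOND_SHELL_CUTOFF,
) -> ShellCounts:
    """First/second hydration-shell water counts for one snapshot."""
    d = water_min_distances(snapshot, scope)
    return ShellCounts(
        time=snapshot.time,
        n_first_shell=int((d < first_cutoff).sum()),
        n_second_shell=int(((d >= first_cutoff) & (d < second_cutoff)).sum()),
    )


def released_waters(
    complex_series: SnapshotSeries,
    freeA_series: SnapshotSeries,
    freeB_series: SnapshotSeries,
    shell: str = "first",
) -> tuple[float, float]:
    """Mean number of shell waters released upon complexation, with SE.

    Returns ``(N_released, standard_error)`` where N_released =
    ⟨N_shell(free A)⟩ + ⟨N_shell(free B)⟩ − ⟨N_shell(complex)⟩ and the
    standard error combines the three series' standard errors of the
    mean in quadrature.
    """
    if shell not in ("first", "second"):
        raise ValueError("shell must be 'first' or 'second'")
    attr = "n_first_shell" if shell == "first" else "n_second_shell"

    def stats(series: SnapshotSeries) -> tuple[float, float]:
        if len(series) == 0:
            raise ValueError("empty snapshot series")
        counts = np.array(
            [getattr(shell_counts(s), attr) for s in series], dtype=float
        )
        se = counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else 0.0
        return counts.mean(), se

    mA, sA = stats(freeA_series)
    mB, sB = stats(freeB_series)
    mAB, sAB = stats(complex_series)
    return mA + mB - mAB, float(np.sqrt(sA**2 + sB**2 + sAB**2))


def interfacial_waters(
    snapshot: Snapshot,
    cutoff: float = INTERFACIAL_CUTOFF,
    chain_pair: tuple[str, str] | None = None,
) -> set[int]:
    """Waters strictly within ``cutoff`` of heavy atoms of both chains."""
    chains = snapshot.chains()
    if chain_pair is None:
        if len(chains) != 2:
            raise ValueError("two chains required")
        chain_pair = (chains[0], chains[1])
    if snapshot.n_waters == 0:
        return set()
    ids = snapshot.water_ids
    out = np.ones(len(ids), dtype=bool)
    for chain in chain_pair:
        d = water_min_distances(snapshot, [chain])
        out &= d < cutoff
    return {int(w) for w in ids[out]}


def _bridges_one(
    snapshot: Snapshot, cutoff: float, chain_pair: tuple[str, str]
) -> set[tuple[ResidueRef, ResidueRef]]:
    """Residue pairs bridged by at least one water in one snapshot."""
    if snapshot.n_waters == 0:
        return set()
    wtree = cKDTree(snapshot.water_xyz)
    near: list[list[set[ResidueRef]]] = []
    for chain in chain_pair:
        mask = snapshot.chain_mask(chain)
        idx = np.flatnonzero(mask)
        hits = cKDTree(snapshot.xyz[mask]).query_ball_tree(wtree, r=cutoff)
        per_water: list[set[ResidueRef]] = [set() for _ in range(snapshot.n_waters)]
        for ai, ws in enumerate(hits):
            ref = (chain, int(snapshot.residue_index[idx[ai]]))
            for w in ws:
                # strict inequality at the cutoff
                if np.linalg.norm(
                    snapshot.xyz[idx[ai]] - snapshot.water_xyz[w]
                ) < cutoff:
                    per_water[w].add(ref)
        near.append(per_water)
    pairs: set[tuple[ResidueRef, ResidueRef]] = set()
    for w in range(snapshot.n_waters):
        for r1 in near[0][w]:
            for r2 in near[1][w]:
                pairs.add((r1, r2))
    return pairs


def water_mediated_contacts(
    series: SnapshotSeries,
    labels: ClusterLabels | None = None,
    cutoff: float = INTERFACIAL_CUTOFF,
    chain_pair: tuple[str, str] | None = None,
    regions: InterfaceRegions | None = None,
) -> pd.DataFrame:
    """Frequency of water-bridged residue pairs, overall and per cluster.

    A pair (i from chain 1, j from chain 2) counts in a snapshot when at
    least one water lies within ``cutoff`` of both residues.  Output
    columns: chain1/resid1/chain2/resid2, cluster (0 = whole
    trajectory), frequency, and region classes when provided.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if labels is not None and len(labels.labels) != len(series):
        raise ValueError("labels do not align with series")
    first = series[0]
    chains = first.chains()
    if chain_pair is None:
        if len(chains) != 2:
            raise ValueError("two chains required")
        chain_pair = (chains[0], chains[1])

    per_snapshot = [_bridges_one(s, cutoff, chain_pair) for s in series]
    all_pairs = sorted({p for s in per_snapshot for p in s})
    groups: dict[int, list[int]] = {0: list(range(len(series)))}
    if labels is not None:
        for c in range(1, labels.n_clusters + 1):
            groups[c] = list(labels.members(c))
    rows = []
    for (r1, r2) in all_pairs:
        for cluster, members in groups.items():
            freq = float(
                np.mean([1.0 if (r1, r2) in per_snapshot[m] else 0.0 for m in members])
            )
            row = {
                "chain1": r1[0], "resid1": r1[1],
                "chain2": r2[0], "resid2": r2[1],
                "cluster": cluster, "frequency": freq,
            }
            if regions is not None:
                row["region1"] = regions.classes.get(r1, "unknown")
                row["region2"] = regions.classes.get(r2, "unknown")
            rows.append(row)
    return pd.DataFrame(rows)


def residue_water_contact_counts(
    series: SnapshotSeries,
    labels: ClusterLabels | None = None,
    interface_residues: InterfaceRegions | list[ResidueRef] | None = None,
    cutoff: float = INTERFACIAL_CUTOFF,
    chain_pair: tuple[str, str] | None = None,
    std_flag: float = 2.0,
) -> pd.DataFrame:
    """Interfacial-water contacts per interface residue, summarised per cluster.

    For every snapshot, each residue's count of interfacial waters
    within ``cutoff`` of its heavy atoms is recorded; per cluster the
    quartiles are reported.  Residues whose counts vary strongly over
    the whole trajectory (std > ``std_flag``) carry a ``variable`` flag.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    first = series[0]
    chains = first.chains()
    if chain_pair is None:
        if len(chains) != 2:
            raise ValueError("two chains required")
        chain_pair = (chains[0], chains[1])
    if interface_residues is None:
        residues = first.residues()
    elif isinstance(interface_residues, InterfaceRegions):
        residues = interface_residues.interface_residues()
    else:
        residues = list(interface_residues)

    counts = {r: np.zeros(len(series)) for r in residues}
    for t, snap in enumerate(series):
        iw = interfacial_waters(snap, cutoff=cutoff, chain_pair=chain_pair)
        if not iw:
            continue
        wmask = np.isin(snap.water_ids, sorted(iw))
        wtree = cKDTree(snap.water_xyz[wmask])
        for r in residues:
            amask = (snap.chain_ids == r[0]) & (snap.residue_index == r[1])
            if not amask.any():
                continue
            hits = wtree.query_ball_point(snap.xyz[amask], cutoff)
            wset = {w for h in hits for w in h}
            counts[r][t] = len(wset)

    groups: dict[int, list[int]] = {0: list(range(len(series)))}
    if labels is not None:
        if len(labels.labels) != len(series):
            raise ValueError("labels do not align with series")
        for c in range(1, labels.n_clusters + 1):
            groups[c] = list(labels.members(c))
    rows = []
    for r in residues:
        overall_std = counts[r].std()
        for cluster, members in groups.items():
            vals = counts[r][members]
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "chain": r[0], "resid": r[1], "cluster": cluster,
                    "mean": float(vals.mean()), "q1": float(q1),
                    "median": float(med), "q3": float(q3),
                    "std_overall": float(overall_std),
                    "variable": bool(overall_std > std_flag),
                }
            )
    return pd.DataFrame(rows)
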