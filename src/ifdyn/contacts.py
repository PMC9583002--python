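"""Cross-chain residue contacts, their conservation, typing and H-bonds.

A contact is a pair of residues, one from each chain, whose closest
heavy atoms lie within a distance cutoff (5 Å by default, boundary
inclusive).  Contact sets are the currency of the downstream substate
analysis: conservation relative to the starting interface, polarity
typing, Jaccard similarity and clustering all operate on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import APOLAR_RESIDUES, POLAR_RESIDUES, is_hbond_acceptor, is_hbond_donor
from .snapshots import Snapshot

__all__ = [
    "ContactSet",
    "ConservationSeries",
    "compute_contacts",
    "conservation_series",
    "contact_type_fractions",
    "count_interface_hbonds",
]

ResidueRef = tuple[str, int]  # (chain id, author residue index)
Contact = tuple[ResidueRef, ResidueRef]


@dataclass(frozen=True)
class ContactSet:
    """Cross-chain residue contacts of one snapshot."""

    contacts: frozenset[Contact]
    time: float = 0.0
    resnames: dict[ResidueRef, str] | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def __contains__(self, item) -> bool:
        return item in self.contacts

    def residues(self) -> set[ResidueRef]:
        return {r for pair in self.contacts for r in pair}


@dataclass
class ConservationSeries:
    """Per-snapshot conservation of the reference interface."""

    times: list[float]
    fraction_initial: list[float]
    n_contacts: list[int]
    type_fractions: list[tuple[float, float, float]]  # (polar-polar, apolar-apolar, mixed)
    reference_index: int = 0


def compute_contacts(
    snapshot: Snapshot,
    cutoff: float = 5.0,
    chain_pair: tuple[str, str] | None = None,
) -> ContactSet:
    """Residue pairs with any heavy-atom distance ≤ ``cutoff`` across chains.

    The pair orientation follows ``chain_pair`` (partner 1, partner 2);
    by default the two chains in order of appearance.
    """
    chains = snapshot.chains()
    if chain_pair is None:
        if len(chains) != 2:
            raise ValueError(
                f"snapshot has {len(chains)} chain(s) {chains}; "
                "two chains (or an explicit chain_pair) are required"
            )
        chain_pair = (chains[0], chains[1])
    c1, c2 = chain_pair
    m1, m2 = snapshot.chain_mask(c1), snapshot.chain_mask(c2)
    if not m1.any() or not m2.any():
        raise ValueError(f"chain pair {chain_pair} not present in {chains}")

    xyz1, xyz2 = snapshot.xyz[m1], snapshot.xyz[m2]
    res1 = snapshot.residue_index[m1]
    res2 = snapshot.residue_index[m2]
    pairs = cKDTree(xyz1).query_ball_tree(cKDTree(xyz2), r=cutoff)
    found: set[Contact] = set()
    for i, js in enumerate(pairs):
        for j in js:
            found.add(((c1, int(res1[i])), (c2, int(res2[j]))))
    return ContactSet(
        contacts=frozenset(found),
        time=snapshot.time,
        resnames=snapshot.residue_names(),
    )


def conservation_series(
    series: list[ContactSet],
    reference_index: int = 0,
    polar_set: frozenset[str] = POLAR_RESIDUES,
) -> ConservationSeries:
    """Fraction of the reference snapshot's contacts retained over time.

    ``fraction_initial[t] = |C_t ∩ C_ref| / |C_ref|``; the contact-type
    composition (polar–polar, apolar–apolar, mixed) is reported per
    snapshot alongside.
    """
    if not series:
        raise ValueError("empty contact series")
    ref = series[reference_index].contacts
    if not ref:
        raise ValueError("reference snapshot has no contacts; fraction undefined")
    times, fracs, counts, types = [], [], [], []
    nan3 = (float("nan"),) * 3
    for cs in series:
        times.append(cs.time)
        fracs.append(len(cs.contacts & ref) / len(ref))
        counts.append(len(cs.contacts))
        # typing needs residue names; label-only sets report NaN fractions
        types.append(
            contact_type_fractions(cs, polar_set=polar_set)
            if cs.resnames is not None
            else nan3
        )
    return ConservationSeries(times, fracs, counts, types, reference_index)


def contact_type_fractions(
    contact_set: ContactSet,
    polar_set: frozenset[str] = POLAR_RESIDUES,
    fallback: str | None = None,
) -> tuple[float, float, float]:
    """Fractions of polar–polar, apolar–apolar and mixed contacts.

    The polarity alphabet is configurable; an unknown residue name
    raises unless ``fallback`` ('polar' or 'apolar') is given.  An empty
    contact set returns (0, 0, 0).
    """
    if not contact_set.contacts:
        return (0.0, 0.0, 0.0)
    if contact_set.resnames is None:
        raise ValueError("contact set carries no residue names")

    def polarity(ref: ResidueRef) -> bool:
        name = contact_set.resnames[ref].upper()
        if name in polar_set:
            return True
        if name in APOLAR_RESIDUES or name in POLAR_RESIDUES:
            return False  # standard residue outside the configured polar set
        if fallback is None:
            raise KeyError(f"residue name {name!r} not classifiable")
        return fallback == "polar"

    pp = aa = mixed = 0
    for r1, r2 in contact_set.contacts:
        p1, p2 = polarity(r1), polarity(r2)
        if p1 and p2:
            pp += 1
        elif not p1 and not p2:
            aa += 1
        else:
            mixed += 1
    n = len(contact_set.contacts)
    return (pp / n, aa / n, mixed / n)


def count_interface_hbonds(
    snapshot: Snapshot,
    chain_pair: tuple[str, str] | None = None,
    da_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> int:
    """Cross-chain hydrogen bonds by geometric criterion.

    A donor–acceptor heavy-atom pair within ``da_cutoff`` Å counts; when
    the snapshot carries hydrogens, the hydrogen–donor–acceptor angle
    must additionally be ≤ ``angle_cutoff`` degrees for some hydrogen
    bonded to the donor.  Without hydrogens the distance criterion alone
    is used.
    """
    chains = snapshot.chains()
    if chain_pair is None:
        if len(chains) != 2:
            raise ValueError("two chains required")
        chain_pair = (chains[0], chains[1])

    def roles(mask):
        don, acc = [], []
        idx = np.flatnonzero(mask)
        for i in idx:
            rn, an = snapshot.residue_name[i], snapshot.atom_name[i]
            if is_hbond_donor(rn, an):
                don.append(i)
            if is_hbond_acceptor(rn, an):
                acc.append(i)
        return np.array(don, dtype=int), np.array(acc, dtype=int)

    m1 = snapshot.chain_mask(chain_pair[0])
    m2 = snapshot.chain_mask(chain_pair[1])
    d1, a1 = roles(m1)
    d2, a2 = roles(m2)

    have_h = snapshot.h_xyz is not None and len(snapshot.h_xyz) > 0

    def donor_hydrogens(i: int) -> np.ndarray:
        # hydrogens of the same residue within covalent range of the donor
        same = (snapshot.h_chain_ids == snapshot.chain_ids[i]) & (
            snapshot.h_residue_index == snapshot.residue_index[i]
        )
        hx = snapshot.h_xyz[same]
        if not len(hx):
            return hx
        d = np.linalg.norm(hx - snapshot.xyz[i], axis=1)
        return hx[d <= 1.25]

    def count(donors: np.ndarray, acceptors: np.ndarray) -> int:
        if not len(donors) or not len(acceptors):
            return 0
        dx = snapshot.xyz[donors]
        ax = snapshot.xyz[acceptors]
        dist = np.linalg.norm(dx[:, None, :] - ax[None, :, :], axis=2)
        n = 0
        for ii, i in enumerate(donors):
            close = np.flatnonzero(dist[ii] <= da_cutoff)
            if not len(close):
                continue
            if not have_h:
                n += len(close)
                continue
            hx = donor_hydrogens(i)
            for jj in close:
                if not len(hx):
                    n += 1  # donor lacks explicit hydrogens: distance only
                    continue
                v_a = ax[jj] - dx[ii]
                v_h = hx - dx[ii]
                cosang = (v_h @ v_a) / (
                    np.linalg.norm(v_h, axis=1) * np.linalg.norm(v_a) + 1e-12
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if (ang <= angle_cutoff).any():
                    n += 1
        return n

    return count(d1, a2) + count(d2, a1)
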