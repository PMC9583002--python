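"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ifdyn.contacts import ContactSet
from ifdyn.snapshots import Snapshot
from ifdyn.synthetic import ToyComplexSpec, gen_toy_complex


def make_snapshot(atoms, waters=(), time=0.0, hydrogens=()):
    """Snapshot from (chain, resid, resname, atom_name, element, xyz) tuples."""
    atoms = list(atoms)
    snap = Snapshot(
        time=time,
        chain_ids=np.array([a[0] for a in atoms], dtype=object),
        residue_index=np.array([a[1] for a in atoms], dtype=np.int64),
        residue_name=np.array([a[2] for a in atoms], dtype=object),
        atom_name=np.array([a[3] for a in atoms], dtype=object),
        element=np.array([a[4] for a in atoms], dtype=object),
        xyz=np.array([a[5] for a in atoms], dtype=float),
        water_ids=np.array([w[0] for w in waters], dtype=np.int64),
        water_xyz=np.array([w[1] for w in waters], dtype=float).reshape(-1, 3),
    )
    if hydrogens:
        snap.h_chain_ids = np.array([h[0] for h in hydrogens], dtype=object)
        snap.h_residue_index = np.array([h[1] for h in hydrogens], dtype=np.int64)
        snap.h_atom_name = np.array([h[2] for h in hydrogens], dtype=object)
        snap.h_xyz = np.array([h[3] for h in hydrogens], dtype=float)
    return snap


def brute_force_contacts(snapshot, cutoff=5.0, chain_pair=None):
    """O(N²) reference for cross-chain residue contacts."""
    chains = snapshot.chains() if chain_pair is None else list(chain_pair)
    c1, c2 = chains[0], chains[1]
    found = set()
    for i in range(snapshot.n_atoms):
        if snapshot.chain_ids[i] != c1:
            continue
        for j in range(snapshot.n_atoms):
            if snapshot.chain_ids[j] != c2:
                continue
            d = np.linalg.norm(snapshot.xyz[i] - snapshot.xyz[j])
            if d <= cutoff:
                found.add(
                    (
                        (c1, int(snapshot.residue_index[i])),
                        (c2, int(snapshot.residue_index[j])),
                    )
                )
    return found


def random_contact_sets(rng, n_sets=8, n_residues=10, p=0.3):
    """Random cross-chain contact sets over a small residue universe."""
    universe = [
        (("A", i), ("B", j))
        for i in range(1, n_residues + 1)
        for j in range(101, 101 + n_residues)
    ]
    out = []
    for t in range(n_sets):
        mask = rng.random(len(universe)) < p
        out.append(
            ContactSet(
                contacts=frozenset(c for c, m in zip(universe, mask) if m),
                time=float(t),
            )
        )
    return out


@pytest.fixture(scope="session")
def toy_complex():
    return gen_toy_complex(ToyComplexSpec(seed=42))


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
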