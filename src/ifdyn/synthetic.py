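"""Synthetic inputs for every pipeline stage: toy complexes, substate
contact series with ground truth, and correlated sample pairs.

The generators emulate the study conditions the analyses were designed
for without requiring trajectories: (i) pseudo-atomic two-chain
complexes with explicit waters in bound and unbound states, (ii)
contact-set time series switching between long-lived hidden substates
with independent per-contact flip noise, and (iii) bivariate normal
draws with a prescribed population correlation.  Everything is
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import APOLAR_RESIDUES, POLAR_RESIDUES
from .contacts import Contact, ContactSet
from .snapshots import Snapshot, SnapshotSeries

__all__ = [
    "SubstateSpec",
    "ToyComplexSpec",
    "gen_contact_series",
    "two_state_spec",
    "gen_toy_complex",
    "gen_toy_series",
    "gen_correlated_pairs",
]

CLASH_DISTANCE = 2.4  # Å, ≈ sum of vdW radii minus typical overlap


@dataclass
class SubstateSpec:
    """Hidden-substate contact-series specification.

    ``dwell_segments`` lists (substate index, number of snapshots) in
    chronological order; within a segment every snapshot's contact set
    is the substate's defining set, then each contact of the universe
    (union of all substate sets plus the decoy pool) is independently
    flipped with probability ``flip_noise``.
    """

    substate_contact_sets: list[frozenset[Contact]]
    dwell_segments: list[tuple[int, int]]
    flip_noise: float = 0.0
    seed: int = 0
    decoy_pairs: frozenset[Contact] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.substate_contact_sets:
            raise ValueError("at least one substate is required")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")
        if not self.dwell_segments or any(n <= 0 for _, n in self.dwell_segments):
            raise ValueError("dwell segments must have positive lengths")
        k = len(self.substate_contact_sets)
        if any(not 0 <= s < k for s, _ in self.dwell_segments):
            raise ValueError("dwell segment refers to an undefined substate")

    @property
    def n_snapshots(self) -> int:
        return sum(n for _, n in self.dwell_segments)

    @property
    def universe(self) -> frozenset[Contact]:
        u: set[Contact] = set(self.decoy_pairs)
        for s in self.substate_contact_sets:
            u |= s
        return frozenset(u)


def gen_contact_series(
    spec: SubstateSpec, dt: float = 1.0
) -> tuple[list[ContactSet], np.ndarray]:
    """Contact-set series following the spec, plus true substate labels."""
    rng = np.random.default_rng(spec.seed)
    universe = sorted(spec.universe)
    series: list[ContactSet] = []
    labels: list[int] = []
    t = 0
    for sub_idx, n in spec.dwell_segments:
        base = spec.substate_contact_sets[sub_idx]
        for _ in range(n):
            if spec.flip_noise > 0:
                flips = rng.random(len(universe)) < spec.flip_noise
                contacts = {
                    c
                    for c, f in zip(universe, flips)
                    if (c in base) != f
                }
            else:
                contacts = set(base)
            series.append(ContactSet(contacts=frozenset(contacts), time=t * dt))
            labels.append(sub_idx)
            t += 1
    return series, np.array(labels, dtype=np.int64)


def two_state_spec(
    n_contacts: int = 30,
    shared_fraction: float = 0.5,
    n_per_state: int = 150,
    flip_noise: float = 0.05,
    n_decoys: int = 10,
    seed: int = 0,
) -> SubstateSpec:
    """Convenience builder: two substates sharing a fraction of contacts.

    Contacts are residue pairs (A, i)–(B, j) on a synthetic numbering;
    each substate holds ``n_contacts`` contacts of which
    ``shared_fraction`` are common to both.
    """
    n_shared = int(round(shared_fraction * n_contacts))
    n_own = n_contacts - n_shared
    total = n_shared + 2 * n_own + n_decoys
    pool = [(("A", i + 1), ("B", i + 101)) for i in range(total)]
    shared = pool[:n_shared]
    own1 = pool[n_shared : n_shared + n_own]
    own2 = pool[n_shared + n_own : n_shared + 2 * n_own]
    decoys = pool[n_shared + 2 * n_own :]
    return SubstateSpec(
        substate_contact_sets=[
            frozenset(shared + own1),
            frozenset(shared + own2),
        ],
        dwell_segments=[(0, n_per_state), (1, n_per_state)],
        flip_noise=flip_noise,
        seed=seed,
        decoy_pairs=frozenset(decoys),
    )


@dataclass
class ToyComplexSpec:
    """Pseudo-atomic two-chain complex with explicit waters.

    Residues are rigid triads (N, CA, C by default) on a jittered
    lattice; the chains face each other across ``interface_gap`` Å and
    waters are rejection-sampled uniformly in the box, discarding
    positions clashing (< 2.4 Å) with any heavy atom.
    """

    n_residues_per_chain: int = 16
    atoms_per_residue: int = 3
    interface_gap: float = 4.0
    n_waters: int = 60
    box: tuple[float, float, float] = (40.0, 30.0, 30.0)
    seed: int = 0
    lattice_spacing: float = 5.0
    jitter: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_residues_per_chain, self.atoms_per_residue) <= 0:
            raise ValueError("counts must be positive")
        if self.n_waters < 0 or self.interface_gap < 0:
            raise ValueError("n_waters and interface_gap must be non-negative")


_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD"]
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C"}
# local triad geometry (Å), roughly bonded spacing
_ATOM_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.2, 0.9, 0.0],
        [2.4, 0.0, 0.0],
        [2.9, -1.0, 0.6],
        [1.2, 1.8, 1.2],
        [1.8, 2.9, 1.8],
        [2.6, 3.8, 2.2],
    ]
)


def _chain_atoms(
    chain_id: str,
    n_res: int,
    atoms_per_res: int,
    origin: np.ndarray,
    facing: int,
    spacing: float,
    jitter: float,
    rng: np.random.Generator,
    first_resid: int,
) -> dict:
    """One chain as a jittered lattice of rigid residue triads."""
    alphabet = sorted(POLAR_RESIDUES) + sorted(APOLAR_RESIDUES)
    side = int(np.ceil(np.sqrt(n_res)))
    rows = {k: [] for k in ("chain", "resid", "resname", "name", "element", "xyz")}
    for r in range(n_res):
        gy, gz = divmod(r, side)
        base = origin + np.array([0.0, gy * spacing, gz * spacing])
        base += rng.normal(0.0, jitter, 3)
        resname = alphabet[int(rng.integers(len(alphabet)))]
        for a in range(atoms_per_res):
            name = _ATOM_NAMES[a % len(_ATOM_NAMES)]
            off = _ATOM_OFFSETS[a % len(_ATOM_OFFSETS)].copy()
            off[0] *= facing  # triads point toward the partner chain
            rows["chain"].append(chain_id)
            rows["resid"].append(first_resid + r)
            rows["resname"].append(resname)
            rows["name"].append(name)
            rows["element"].append(_ATOM_ELEMENTS[name])
            rows["xyz"].append(base + off)
    return rows


def _place_waters(
    n: int,
    box: tuple[float, float, float],
    center: np.ndarray,
    protein_xyz: np.ndarray,
    rng: np.random.Generator,
    first_id: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial import cKDTree

    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, 3))
    tree = cKDTree(protein_xyz) if len(protein_xyz) else None
    lo = center - np.asarray(box) / 2
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(200 * n, 2000)
    while len(placed) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} waters in box {box}: only "
                f"{len(placed)} fit without clashes"
            )
        pos = lo + rng.random(3) * np.asarray(box)
        attempts += 1
        if tree is not None and tree.query(pos, k=1)[0] < CLASH_DISTANCE:
            continue
        if placed and np.min(
            np.linalg.norm(np.asarray(placed) - pos, axis=1)
        ) < CLASH_DISTANCE:
            continue  # waters keep clash distance among themselves too
        placed.append(pos)
    ids = np.arange(first_id, first_id + n, dtype=np.int64)
    return ids, np.asarray(placed)


def _snapshot_from_rows(rows: dict, wids, wxyz, time: float = 0.0) -> Snapshot:
    return Snapshot(
        time=time,
        chain_ids=np.array(rows["chain"], dtype=object),
        residue_index=np.array(rows["resid"], dtype=np.int64),
        residue_name=np.array(rows["resname"], dtype=object),
        atom_name=np.array(rows["name"], dtype=object),
        element=np.array(rows["element"], dtype=object),
        xyz=np.asarray(rows["xyz"]),
        water_ids=wids,
        water_xyz=wxyz,
    )


def gen_toy_complex(spec: ToyComplexSpec) -> tuple[Snapshot, Snapshot, Snapshot]:
    """Bound complex and the two unbound chains, each with its own waters.

    Chain A's triads point toward +x and end at x ≈ 0; chain B's start
    at x ≈ interface_gap pointing toward −x, so the smallest cross-chain
    heavy-atom distance is approximately ``interface_gap``.  Unbound
    forms reuse the chain coordinates with independently sampled waters.
    """
    rng = np.random.default_rng(spec.seed)
    span = _ATOM_OFFSETS[: min(spec.atoms_per_residue, len(_ATOM_OFFSETS)), 0].max()
    rows_a = _chain_atoms(
        "A", spec.n_residues_per_chain, spec.atoms_per_residue,
        np.array([-span, 0.0, 0.0]), +1,
        spec.lattice_spacing, spec.jitter, rng, first_resid=1,
    )
    rows_b = _chain_atoms(
        "B", spec.n_residues_per_chain, spec.atoms_per_residue,
        np.array([span + spec.interface_gap, 0.0, 0.0]), -1,
        spec.lattice_spacing, spec.jitter, rng, first_resid=101,
    )
    both = {k: rows_a[k] + rows_b[k] for k in rows_a}
    pxyz = np.asarray(both["xyz"])
    center = pxyz.mean(axis=0)
    wids, wxyz = _place_waters(spec.n_waters, spec.box, center, pxyz, rng)
    complex_snap = _snapshot_from_rows(both, wids, wxyz)

    unbound = []
    for rows in (rows_a, rows_b):
        cxyz = np.asarray(rows["xyz"])
        uids, uxyz = _place_waters(
            spec.n_waters, spec.box, cxyz.mean(axis=0), cxyz, rng
        )
        unbound.append(_snapshot_from_rows(rows, uids, uxyz))
    return complex_snap, unbound[0], unbound[1]


def gen_toy_series(
    spec: ToyComplexSpec,
    n_snapshots: int = 10,
    dt: float = 1.0,
    coord_jitter: float = 0.15,
) -> tuple[SnapshotSeries, SnapshotSeries, SnapshotSeries]:
    """Short pseudo-trajectories of the toy system (complex + unbound).

    Each frame adds isotropic Gaussian jitter to the atom coordinates
    and re-samples the water positions, mimicking thermal motion and
    water exchange without any force field.
    """
    rng = np.random.default_rng(spec.seed + 1)
    c0, a0, b0 = gen_toy_complex(spec)

    def series_of(base: Snapshot, source: str) -> SnapshotSeries:
        snaps = []
        for t in range(n_snapshots):
            xyz = base.xyz + rng.normal(0.0, coord_jitter, base.xyz.shape)
            wids, wxyz = _place_waters(
                len(base.water_ids), spec.box, xyz.mean(axis=0), xyz, rng
            )
            snaps.append(
                Snapshot(
                    time=t * dt,
                    chain_ids=base.chain_ids,
                    residue_index=base.residue_index,
                    residue_name=base.residue_name,
                    atom_name=base.atom_name,
                    element=base.element,
                    xyz=xyz,
                    water_ids=wids,
                    water_xyz=wxyz,
                )
            )
        return SnapshotSeries(snapshots=snaps, dt=dt, source=source)

    return (
        series_of(c0, "complex"),
        series_of(a0, "unbound_A"),
        series_of(b0, "unbound_B"),
    )


def gen_correlated_pairs(
    n: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard normal draws with population correlation rho."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be ≤ 1")
    if n < 3:
        raise ValueError("n must be ≥ 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = rho * x + np.sqrt(max(1.0 - rho * rho, 0.0)) * z
    return x, y
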