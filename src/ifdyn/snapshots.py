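"""In-memory representation of trajectory snapshots.

A :class:`Snapshot` holds the heavy atoms of a (usually two-chain)
protein system plus the oxygen positions of the surrounding waters at a
single time point.  A :class:`SnapshotSeries` is a time-ordered list of
snapshots sharing one topology, the unit every per-trajectory analysis
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Snapshot", "SnapshotSeries"]


@dataclass
class Snapshot:
    """Heavy atoms of a protein system plus water oxygens at one time.

    Parameters
    ----------
    time:
        Time of the frame in nanoseconds.
    chain_ids, residue_index, residue_name, atom_name, element:
        Per-atom annotation arrays (length ``n_atoms``).  Residue indices
        follow the source file's author numbering; no renumbering is done.
    xyz:
        ``(n_atoms, 3)`` heavy-atom coordinates in Å.
    water_ids, water_xyz:
        Water identifiers and oxygen coordinates, ``(n_waters,)`` and
        ``(n_waters, 3)``.
    h_chain_ids, h_residue_index, h_atom_name, h_xyz:
        Optional protein hydrogens, kept out of ``xyz`` so that every
        heavy-atom analysis can ignore them; used only for hydrogen-bond
        angle checks.
    """

    time: float
    chain_ids: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    water_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    water_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    h_chain_ids: np.ndarray | None = None
    h_residue_index: np.ndarray | None = None
    h_atom_name: np.ndarray | None = None
    h_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.water_xyz = np.asarray(self.water_xyz, dtype=np.float64).reshape(-1, 3)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.water_ids = np.asarray(self.water_ids, dtype=np.int64)
        n = len(self.xyz)
        for arr, label in [
            (self.chain_ids, "chain_ids"),
            (self.residue_index, "residue_index"),
            (self.residue_name, "residue_name"),
            (self.atom_name, "atom_name"),
            (self.element, "element"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if len(self.water_ids) != len(self.water_xyz):
            raise ValueError("water_ids and water_xyz lengths differ")
        if n and not np.isfinite(self.xyz).all():
            raise ValueError("non-finite heavy-atom coordinates")
        if len(self.water_xyz) and not np.isfinite(self.water_xyz).all():
            raise ValueError("non-finite water coordinates")

    # -- convenience accessors ------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    @property
    def n_waters(self) -> int:
        return len(self.water_ids)

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def chain_xyz(self, chain_id: str) -> np.ndarray:
        return self.xyz[self.chain_mask(chain_id)]

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int]]:
        """Unique (chain, residue index) keys, in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.residue_index):
            if chain_id is None or c == chain_id:
                seen.setdefault((c, int(r)), None)
        return list(seen)

    def residue_names(self) -> dict[tuple[str, int], str]:
        """Map (chain, residue index) -> 3-letter residue name."""
        out: dict[tuple[str, int], str] = {}
        for c, r, nm in zip(self.chain_ids, self.residue_index, self.residue_name):
            out.setdefault((c, int(r)), str(nm))
        return out

    def subset(self, mask: np.ndarray, *, keep_waters: bool = True) -> "Snapshot":
        """New snapshot restricted to the atoms selected by ``mask``."""
        return Snapshot(
            time=self.time,
            chain_ids=self.chain_ids[mask],
            residue_index=self.residue_index[mask],
            residue_name=self.residue_name[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            xyz=self.xyz[mask],
            water_ids=self.water_ids if keep_waters else np.empty(0, dtype=np.int64),
            water_xyz=self.water_xyz if keep_waters else np.empty((0, 3)),
        )

    def chain_subset(self, chain_id: str, *, keep_waters: bool = False) -> "Snapshot":
        return self.subset(self.chain_mask(chain_id), keep_waters=keep_waters)


@dataclass
class SnapshotSeries:
    """Time-ordered snapshots of one system (complex or unbound chain)."""

    snapshots: list[Snapshot]
    dt: float = 1.0
    source: str = "complex"

    def __post_init__(self) -> None:
        times = [s.time for s in self.snapshots]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        comps = {(s.n_atoms, tuple(s.chains())) for s in self.snapshots}
        if len(comps) > 1:
            raise ValueError("snapshots differ in atom composition (topology)")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])
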