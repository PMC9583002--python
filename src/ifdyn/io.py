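"""Reading structures/trajectories into snapshots, and tabular output.

Parsing of every standard format (single- and multi-model PDB, GRO/PDB
topology plus XTC/DCD trajectories) is delegated to MDAnalysis; this
module only converts frames into the pipeline's :class:`Snapshot`
representation: heavy protein atoms of the requested chains, water
oxygens (residue names HOH/WAT/SOL/TIP3/TIP, case-insensitive), ions
discarded, hydrogens kept aside for hydrogen-bond geometry.

Periodic-boundary treatment is assumed done upstream: each chain must be
whole and the complex re-imaged before loading.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._tables import WATER_RESNAMES
from .snapshots import Snapshot, SnapshotSeries

__all__ = ["load_series", "write_table", "read_table", "write_pdb", "write_json"]

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "FE", "ZN", "SE", "CA", "MN", "CU", "NI", "CO", "LI",
}


def infer_element(atom_name: str) -> str:
    """Element from a PDB-convention atom name when no element column exists.

    Digits and primes are stripped; a leading two-letter symbol is
    recognised only for non-protein elements (so CA is carbon-alpha, not
    calcium, inside amino-acid residues — callers pass protein atoms).
    """
    name = atom_name.strip().upper()
    name = name.lstrip("0123456789")
    if not name:
        return "X"
    if name[:2] in _TWO_LETTER_ELEMENTS and name[:2] not in {"CA", "CO", "NI"}:
        return name[:2]
    return name[0]


def _frame_snapshot(
    protein, waters, hydrogens, chain_of, time_ns: float
) -> Snapshot:
    water_ids = waters.resids.astype(np.int64) if len(waters) else np.empty(0, np.int64)
    snap = Snapshot(
        time=time_ns,
        chain_ids=np.array([chain_of(a) for a in protein], dtype=object),
        residue_index=protein.resids.astype(np.int64),
        residue_name=np.array([r.upper() for r in protein.resnames], dtype=object),
        atom_name=np.array(list(protein.names), dtype=object),
        element=np.array([infer_element(n) for n in protein.names], dtype=object),
        xyz=protein.positions.astype(np.float64),
        water_ids=water_ids,
        water_xyz=waters.positions.astype(np.float64)
        if len(waters)
        else np.empty((0, 3)),
    )
    if len(hydrogens):
        snap.h_chain_ids = np.array([chain_of(a) for a in hydrogens], dtype=object)
        snap.h_residue_index = hydrogens.resids.astype(np.int64)
        snap.h_atom_name = np.array(list(hydrogens.names), dtype=object)
        snap.h_xyz = hydrogens.positions.astype(np.float64)
    return snap


def load_series(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    chain_selection: tuple[str, str] | None = None,
    stride: float = 1.0,
    frame_dt: float = 1.0,
    source: str = "complex",
) -> SnapshotSeries:
    """Load a structure (and optional trajectory) into a snapshot series.

    Parameters
    ----------
    structure_path:
        PDB (single- or multi-model) or GRO file; used as topology when
        ``trajectory_path`` is given.
    trajectory_path:
        Optional XTC/DCD/multi-PDB trajectory.
    chain_selection:
        The two protein chain labels to keep, in partner-1/partner-2
        order.  ``None`` keeps every protein chain (needed for unbound
        single-chain runs).
    stride:
        Desired sampling interval in ns; the nearest frame to each
        multiple is selected when the frame spacing does not divide it.
    frame_dt:
        Fallback frame spacing in ns when the file carries no usable
        time information (e.g. multi-model PDB).
    """
    import MDAnalysis as mda

    paths = [str(structure_path)] + (
        [str(trajectory_path)] if trajectory_path else []
    )
    u = mda.Universe(*paths)

    water_sel = " ".join(sorted(WATER_RESNAMES))
    waters_all = u.select_atoms(f"resname {water_sel}")
    water_oxy = waters_all.select_atoms("name O* OH2 OW")
    protein_all = u.select_atoms("protein")

    has_chainids = hasattr(u.atoms, "chainIDs") and any(
        str(c).strip() for c in protein_all.chainIDs
    ) if len(protein_all) else False

    def chain_of(atom) -> str:
        if has_chainids and str(atom.chainID).strip():
            return str(atom.chainID).strip()
        return str(atom.segid).strip() or "A"

    available = []
    for a in protein_all:
        c = chain_of(a)
        if c not in available:
            available.append(c)
    if chain_selection is not None:
        missing = [c for c in chain_selection if c not in available]
        if missing:
            raise ValueError(
                f"chain(s) {missing} not found; available chains: {available}"
            )
        keep = list(chain_selection)
    else:
        keep = available
    mask = np.array([chain_of(a) in keep for a in protein_all], dtype=bool)
    protein_sel = protein_all[mask]

    is_h = np.array(
        [infer_element(n) == "H" for n in protein_sel.names], dtype=bool
    )
    heavy = protein_sel[~is_h]
    hydro = protein_sel[is_h]
    if len(heavy) == 0:
        raise ValueError("no protein heavy atoms after chain selection")

    # frame times in ns; a structure-only multi-model file carries no real
    # time axis, so models are spaced frame_dt apart
    n_frames = len(u.trajectory)
    if trajectory_path is None:
        times = np.arange(n_frames) * frame_dt
    else:
        times = np.empty(n_frames)
        for i, ts in enumerate(u.trajectory):
            times[i] = ts.time / 1000.0  # MDAnalysis reports ps
        if n_frames > 1 and (not np.all(np.isfinite(times)) or np.ptp(times) <= 0):
            times = np.arange(n_frames) * frame_dt
        elif n_frames == 1 and not np.isfinite(times[0]):
            times = np.array([0.0])

    # nearest-frame striding
    if n_frames == 1:
        frame_ids = [0]
    else:
        targets = np.arange(times[0], times[-1] + 1e-9, stride)
        frame_ids = sorted({int(np.argmin(np.abs(times - t))) for t in targets})
    if not frame_ids:
        raise ValueError("zero snapshots selected after striding")

    snapshots = []
    for i in frame_ids:
        u.trajectory[i]
        snapshots.append(_frame_snapshot(heavy, water_oxy, hydro, chain_of, times[i]))
    # guard against duplicate times from coarse time stamps
    for k in range(1, len(snapshots)):
        if snapshots[k].time <= snapshots[k - 1].time:
            snapshots[k].time = snapshots[k - 1].time + frame_dt
    return SnapshotSeries(snapshots=snapshots, dt=stride, source=source)


# --- tabular / structured output -------------------------------------------


def write_table(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a deterministic CSV (UTF-8, '.' decimals).

    Rows are ordered by the time column when present, then by the
    remaining columns lexicographically, so repeated runs are
    byte-identical.  An empty record list yields a header-only file
    (``columns`` must then be given unless records is a DataFrame).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if len(df):
        time_cols = [c for c in ("time_ns", "time") if c in df.columns]
        others = sorted(c for c in df.columns if c not in time_cols)
        by = time_cols + others
        if by:
            df = df.sort_values(by=by, kind="mergesort")
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_pdb(snapshots: Iterable[Snapshot], path: str | Path) -> None:
    """Write snapshots as a multi-model PDB (waters as HOH oxygens, chain W)."""
    snapshots = list(snapshots)
    with open(path, "w", encoding="utf-8") as fh:
        for model, snap in enumerate(snapshots, start=1):
            if len(snapshots) > 1:
                fh.write(f"MODEL     {model:4d}\n")
            serial = 1
            for c, ri, rn, an, el, (x, y, z) in zip(
                snap.chain_ids,
                snap.residue_index,
                snap.residue_name,
                snap.atom_name,
                snap.element,
                snap.xyz,
            ):
                name = f" {an:<3s}" if len(an) < 4 else an[:4]
                fh.write(
                    f"ATOM  {serial % 100000:5d} {name}{'':1s}{rn:>3s} "
                    f"{str(c)[:1]}{int(ri) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}\n"
                )
                serial += 1
            for wid, (x, y, z) in zip(snap.water_ids, snap.water_xyz):
                fh.write(
                    f"HETATM{serial % 100000:5d}  O   HOH W{int(wid) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"           O\n"
                )
                serial += 1
            fh.write("TER\n")
            if len(snapshots) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")
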