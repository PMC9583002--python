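"""ASA quadrature, ΔASA, Levy regions, gap volume and interface RMSD."""

from __future__ import annotations

import numpy as np
import pytest

from ifdyn.geometry import (
    AsaTable,
    atom_asa,
    classify_regions,
    compute_asa,
    delta_asa,
    gap_descriptors,
    gap_index,
    interface_asa,
    interface_rmsd,
    kabsch_rmsd,
    sphere_points,
)
from ifdyn.synthetic import ToyComplexSpec, gen_toy_complex

from conftest import make_snapshot

R_C = 1.87 + 1.4  # extended radius of an aliphatic carbon


class TestShrakeRupley:
    def test_single_atom_matches_analytic_sphere(self):
        snap = make_snapshot([("A", 1, "ALA", "CB", "C", (0, 0, 0))])
        area = atom_asa(snap)[0]
        assert area == pytest.approx(4 * np.pi * R_C**2, rel=0.02)

    def test_two_distant_atoms_are_isolated(self):
        snap = make_snapshot(
            [
                ("A", 1, "ALA", "CB", "C", (0, 0, 0)),
                ("A", 2, "ALA", "CB", "C", (50, 0, 0)),
            ]
        )
        areas = atom_asa(snap)
        assert np.allclose(areas, 4 * np.pi * R_C**2, rtol=0.02)

    def test_two_overlapping_spheres_analytic(self):
        """Equal spheres at distance d: exposed area 4πR² − 2πR(R − d/2)."""
        d = 2.0
        snap = make_snapshot(
            [
                ("A", 1, "ALA", "CB", "C", (0, 0, 0)),
                ("A", 1, "ALA", "CG", "C", (d, 0, 0)),
            ]
        )
        analytic = 4 * np.pi * R_C**2 - 2 * np.pi * R_C * (R_C - d / 2)
        assert np.allclose(atom_asa(snap), analytic, rtol=0.02)

    def test_matches_independent_implementation(self, toy_complex):
        """Cross-check against biotite's SASA with identical radii."""
        import biotite.structure as struc

        from ifdyn.geometry import _radii

        snap, _, _ = toy_complex
        arr = struc.AtomArray(snap.n_atoms)
        arr.coord = snap.xyz.astype(np.float32)
        arr.chain_id = np.array([str(c) for c in snap.chain_ids])
        arr.res_id = snap.residue_index
        arr.res_name = np.array([str(r) for r in snap.residue_name])
        arr.atom_name = np.array([str(a) for a in snap.atom_name])
        arr.element = np.array([str(e) for e in snap.element])
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=_radii(snap), point_number=960)
        mine = atom_asa(snap)
        assert mine.sum() == pytest.approx(ref.sum(), rel=0.01)
        assert np.abs(mine - ref).max() < 2.0

    def test_unknown_element_raises_naming_atom(self):
        snap = make_snapshot([("A", 1, "UNK", "QQ", "Q", (0, 0, 0))])
        with pytest.raises(ValueError, match="QQ"):
            atom_asa(snap)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)


class TestDeltaAsa:
    def test_arithmetic(self):
        assert delta_asa(600.0, 500.0, 300.0) == pytest.approx(800.0)

    def test_separated_chains_zero(self):
        snap, _, _ = gen_toy_complex(ToyComplexSpec(interface_gap=30.0, seed=1, n_waters=0))
        table = interface_asa(snap)
        assert table.delta_asa == pytest.approx(0.0, abs=1e-6)

    def test_bound_toy_matches_context_recomputation(self, toy_complex):
        snap, _, _ = toy_complex
        table = interface_asa(snap)
        _, _, totA = compute_asa(snap.chain_subset("A"))
        _, _, totB = compute_asa(snap.chain_subset("B"))
        _, _, totAB = compute_asa(snap)
        assert table.delta_asa == pytest.approx(totA + totB - totAB, abs=1e-9)
        assert table.delta_asa > 100  # planted interface buries real area

    def test_negative_beyond_tolerance_raises(self):
        with pytest.raises(ValueError):
            delta_asa(100.0, 100.0, 300.0)

    def test_buried_area_grows_as_chains_approach(self):
        values = [
            interface_asa(
                gen_toy_complex(
                    ToyComplexSpec(interface_gap=g, seed=1, n_waters=0)
                )[0]
            ).delta_asa
            for g in (12.0, 8.0, 5.0, 3.0)
        ]
        assert all(b > a - 1e-6 for a, b in zip(values, values[1:]))

    def test_per_residue_asa_never_grows_in_complex(self, toy_complex):
        snap, _, _ = toy_complex
        t = interface_asa(snap)
        for res in t.residues:
            assert t.abs_complex[res] <= t.abs_isolated[res] + 0.5


class TestRegions:
    def _table(self, rel_iso, rel_cplx, d_abs=10.0):
        res = ("A", 1)
        return AsaTable(
            residues=[res],
            resnames={res: "ALA"},
            abs_isolated={res: d_abs + 5.0},
            abs_complex={res: 5.0},
            rel_isolated={res: rel_iso},
            rel_complex={res: rel_cplx},
            asa_A=0.0, asa_B=0.0, asa_AB=0.0, chain_pair=("A", "B"),
        )

    @pytest.mark.parametrize(
        "rel_iso,rel_cplx,expected",
        [
            (10.0, 5.0, "support"),
            (10.0, 24.0, "support"),
            (40.0, 10.0, "core"),
            (60.0, 40.0, "rim"),
            (25.0, 10.0, "rim"),  # boundary tie falls to the catch-all
        ],
    )
    def test_levy_rules(self, rel_iso, rel_cplx, expected):
        out = classify_regions(self._table(rel_iso, rel_cplx))
        assert out.classes[("A", 1)] == expected

    def test_no_asa_change_is_non_interface(self):
        res = ("A", 1)
        t = AsaTable(
            residues=[res], resnames={res: "ALA"},
            abs_isolated={res: 50.0}, abs_complex={res: 50.0},
            rel_isolated={res: 40.0}, rel_complex={res: 40.0},
            asa_A=0, asa_B=0, asa_AB=0, chain_pair=("A", "B"),
        )
        assert classify_regions(t).classes[res] == "non_interface"

    def test_rigid_motion_invariance(self, toy_complex):
        """Classes unchanged by rigid motion, away from threshold boundaries.

        The quadrature grid is fixed in the lab frame, so a residue whose
        relative ASA sits within noise of the 25% threshold may flip; the
        invariance is asserted for all clearly classified residues.
        """
        snap, _, _ = toy_complex
        table = interface_asa(snap)
        ref = classify_regions(table).classes
        rot = _rotation(0.7, 0.3, 1.1)
        moved = _transform(snap, rot, np.array([5.0, -3.0, 8.0]))
        new = classify_regions(interface_asa(moved)).classes
        clear = [
            r
            for r in table.residues
            if abs(table.rel_isolated[r] - 25) > 1 and abs(table.rel_complex[r] - 25) > 1
        ]
        assert len(clear) >= 10
        assert all(new[r] == ref[r] for r in clear)


class TestGapDescriptors:
    def test_gap_index_arithmetic(self):
        assert gap_index(700.0, 1000.0) == pytest.approx(1.4)

    def test_undefined_without_buried_area(self):
        assert gap_index(100.0, 0.0) is None

    def test_tight_planes_have_zero_gap_volume(self):
        # two flat complementary sheets 3 Å apart: no sphere of radius ≥1 Å fits
        atoms = []
        for i in range(5):
            for j in range(5):
                atoms.append(("A", i * 5 + j + 1, "ALA", "CB", "C", (0.0, 2.0 * i, 2.0 * j)))
                atoms.append(("B", i * 5 + j + 101, "ALA", "CB", "C", (3.0, 2.0 * i, 2.0 * j)))
        gd = gap_descriptors(make_snapshot(atoms), delta_asa_value=500.0)
        assert gd.gap_volume == 0.0
        assert gd.gap_index == 0.0

    def test_planted_spherical_cavity_volume(self):
        """Hollow cavity of radius 3 Å → union volume ≈ 4/3·π·27 within 10%."""
        pts = sphere_points(240)
        centers = pts * (3.0 + 1.87)
        atoms = []
        for i, c in enumerate(centers):
            chain = "A" if c[2] >= 0 else "B"
            rid = i + 1 if chain == "A" else i + 101
            atoms.append((chain, rid, "ALA", "CB", "C", tuple(c)))
        gd = gap_descriptors(make_snapshot(atoms), delta_asa_value=1000.0)
        assert gd.gap_volume == pytest.approx(4 / 3 * np.pi * 27, rel=0.10)


def _rotation(a, b, c):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _transform(snap, rot, trans):
    import copy

    out = copy.deepcopy(snap)
    out.xyz = snap.xyz @ rot.T + trans
    if len(out.water_xyz):
        out.water_xyz = snap.water_xyz @ rot.T + trans
    return out


class TestInterfaceRmsd:
    def test_identical_snapshots_zero(self, toy_complex):
        snap, _, _ = toy_complex
        assert interface_rmsd(snap, snap) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self, toy_complex):
        snap, _, _ = toy_complex
        moved = _transform(snap, _rotation(0.4, 1.2, -0.6), np.array([10.0, -4.0, 2.0]))
        assert interface_rmsd(snap, moved) == pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_superposition(self, toy_complex, rng):
        """Perturbed snapshot vs MDAnalysis' superposed RMSD on the same set."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        snap, _, _ = toy_complex
        import copy

        other = copy.deepcopy(snap)
        other.xyz = snap.xyz + rng.normal(0, 0.5, snap.xyz.shape)
        # reproduce the fixed interface backbone set, then compare optima
        from scipy.spatial import cKDTree

        m1, m2 = snap.chain_mask("A"), snap.chain_mask("B")
        sdm = cKDTree(snap.xyz[m1]).sparse_distance_matrix(
            cKDTree(snap.xyz[m2]), max_distance=10.0
        )
        idx1, idx2 = np.flatnonzero(m1), np.flatnonzero(m2)
        iface = set()
        for (i, j), _ in sdm.items():
            iface.add(("A", int(snap.residue_index[idx1[i]])))
            iface.add(("B", int(snap.residue_index[idx2[j]])))
        sel = np.array(
            [
                (snap.chain_ids[k], int(snap.residue_index[k])) in iface
                and snap.atom_name[k] in ("N", "CA", "C", "O")
                for k in range(snap.n_atoms)
            ]
        )
        expected = mda_rmsd(other.xyz[sel], snap.xyz[sel], superposition=True)
        assert interface_rmsd(snap, other) == pytest.approx(expected, abs=1e-6)

    def test_empty_interface_raises(self):
        snap, _, _ = gen_toy_complex(
            ToyComplexSpec(interface_gap=50.0, seed=2, n_waters=0)
        )
        with pytest.raises(ValueError):
            interface_rmsd(snap, snap)

    def test_kabsch_recovers_pure_rotation(self, rng):
        a = rng.normal(size=(20, 3))
        b = a @ _rotation(0.3, -0.8, 0.5).T + np.array([1.0, 2.0, 3.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
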