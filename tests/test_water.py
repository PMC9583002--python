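"""Hydration shells, released waters, interfacial waters and bridges."""

from __future__ import annotations

import numpy as np
import pytest

from ifdyn.clustering import ClusterLabels
from ifdyn.snapshots import SnapshotSeries
from ifdyn.synthetic import ToyComplexSpec, gen_toy_complex, gen_toy_series
from ifdyn.water import (
    interfacial_waters,
    released_waters,
    residue_water_contact_counts,
    shell_counts,
    water_mediated_contacts,
    water_min_distances,
)

from conftest import make_snapshot

ATOM = ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))


class TestShells:
    @pytest.mark.parametrize(
        "d,first,second",
        [(3.0, 1, 0), (3.3999, 1, 0), (3.4, 0, 1), (4.0, 0, 1), (4.999, 0, 1), (5.0, 0, 0), (6.0, 0, 0)],
    )
    def test_half_open_binning(self, d, first, second):
        snap = make_snapshot([ATOM], waters=[(1, (d, 0.0, 0.0))])
        sc = shell_counts(snap)
        assert (sc.n_first_shell, sc.n_second_shell) == (first, second)

    def test_each_water_in_at_most_one_shell(self, toy_complex):
        snap, _, _ = toy_complex
        sc = shell_counts(snap)
        d = water_min_distances(snap)
        assert sc.n_first_shell + sc.n_second_shell <= snap.n_waters
        assert sc.n_first_shell == int((d < 3.4).sum())

    def test_counts_match_brute_force(self, toy_complex):
        snap, _, _ = toy_complex
        d = np.linalg.norm(
            snap.water_xyz[:, None, :] - snap.xyz[None, :, :], axis=2
        ).min(axis=1)
        sc = shell_counts(snap)
        assert sc.n_first_shell == int((d < 3.4).sum())
        assert sc.n_second_shell == int(((d >= 3.4) & (d < 5.0)).sum())

    def test_scope_restricts_chains(self, toy_complex):
        snap, _, _ = toy_complex
        both = shell_counts(snap)
        only_a = shell_counts(snap, scope=["A"])
        assert only_a.n_first_shell <= both.n_first_shell + both.n_second_shell


class TestReleasedWaters:
    def _series(self, snap):
        return SnapshotSeries(snapshots=[snap], dt=1.0)

    def test_disjoint_union_releases_nothing(self):
        """Bound state = far-apart union of the free states → exactly 0."""
        _, free_a, free_b = gen_toy_complex(ToyComplexSpec(seed=8))
        shift = np.array([500.0, 0.0, 0.0])
        merged = make_snapshot(
            [
                (c, int(r), str(rn), str(an), str(el), tuple(x))
                for c, r, rn, an, el, x in zip(
                    free_a.chain_ids, free_a.residue_index, free_a.residue_name,
                    free_a.atom_name, free_a.element, free_a.xyz,
                )
            ]
            + [
                (c, int(r), str(rn), str(an), str(el), tuple(x + shift))
                for c, r, rn, an, el, x in zip(
                    free_b.chain_ids, free_b.residue_index, free_b.residue_name,
                    free_b.atom_name, free_b.element, free_b.xyz,
                )
            ],
            waters=[(int(w), tuple(x)) for w, x in zip(free_a.water_ids, free_a.water_xyz)]
            + [
                (int(w) + 1000, tuple(x + shift))
                for w, x in zip(free_b.water_ids, free_b.water_xyz)
            ],
        )
        n, se = released_waters(
            self._series(merged), self._series(free_a), self._series(free_b), "first"
        )
        assert n == 0.0

    def test_planted_occlusion_counts(self):
        """Free forms carry k first-shell waters each; bound form has none."""
        k = 4
        free_a = make_snapshot(
            [ATOM], waters=[(i + 1, (3.0, 0.5 * i, 0.0)) for i in range(k)]
        )
        free_b = make_snapshot(
            [("B", 2, "GLY", "CA", "C", (0.0, 0.0, 0.0))],
            waters=[(i + 1, (3.0, 0.5 * i, 0.0)) for i in range(k)],
        )
        bound = make_snapshot([ATOM, ("B", 2, "GLY", "CA", "C", (4.0, 0.0, 0.0))])
        n, _ = released_waters(
            self._series(bound), self._series(free_a), self._series(free_b), "first"
        )
        assert n == pytest.approx(2 * k)

    def test_zero_waters_everywhere(self):
        c, a, b = gen_toy_complex(ToyComplexSpec(n_waters=0, seed=0))
        n, se = released_waters(self._series(c), self._series(a), self._series(b))
        assert (n, se) == (0.0, 0.0)

    def test_invalid_shell_name(self):
        c, a, b = gen_toy_complex(ToyComplexSpec(n_waters=0, seed=0))
        with pytest.raises(ValueError):
            released_waters(self._series(c), self._series(a), self._series(b), "third")


class TestInterfacialWaters:
    def test_close_to_both_chains_included(self):
        snap = make_snapshot(
            [ATOM, ("B", 2, "GLY", "CA", "C", (6.0, 0.0, 0.0))],
            waters=[(7, (3.0, 0.0, 0.0))],
        )
        assert interfacial_waters(snap) == {7}

    def test_close_to_one_chain_only_excluded(self):
        snap = make_snapshot(
            [ATOM, ("B", 2, "GLY", "CA", "C", (9.0, 0.0, 0.0))],
            waters=[(7, (3.0, 0.0, 0.0))],
        )
        assert interfacial_waters(snap) == set()

    def test_boundary_strictly_below_cutoff(self):
        snap = make_snapshot(
            [ATOM, ("B", 2, "GLY", "CA", "C", (8.0, 0.0, 0.0))],
            waters=[(7, (4.0, 0.0, 0.0))],
        )
        assert interfacial_waters(snap) == set()

    def test_matches_brute_force(self, toy_complex):
        snap, _, _ = toy_complex
        da = np.linalg.norm(
            snap.water_xyz[:, None, :] - snap.xyz[snap.chain_mask("A")][None], axis=2
        ).min(axis=1)
        db = np.linalg.norm(
            snap.water_xyz[:, None, :] - snap.xyz[snap.chain_mask("B")][None], axis=2
        ).min(axis=1)
        expected = {
            int(w) for w, x, y in zip(snap.water_ids, da, db) if x < 4.0 and y < 4.0
        }
        assert interfacial_waters(snap) == expected

    def test_subset_of_first_two_shells(self, toy_complex):
        snap, _, _ = toy_complex
        d = water_min_distances(snap)
        shell_ids = {int(w) for w, x in zip(snap.water_ids, d) if x < 5.0}
        assert interfacial_waters(snap) <= shell_ids


def _bridge_system(n_frames=5, with_bridge=lambda t: True):
    """Residue A1 and B2 bridged by water 7 in the selected frames."""
    snaps = []
    for t in range(n_frames):
        waters = [(7, (3.0, 0.0, 0.0))] if with_bridge(t) else [(7, (3.0, 30.0, 0.0))]
        snaps.append(
            make_snapshot(
                [
                    ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                    ("B", 2, "GLY", "CA", "C", (6.0, 0.0, 0.0)),
                ],
                waters=waters,
                time=float(t),
            )
        )
    return SnapshotSeries(snapshots=snaps, dt=1.0)


class TestBridges:
    def test_static_bridge_frequency_one(self):
        df = water_mediated_contacts(_bridge_system())
        row = df[(df["cluster"] == 0)].iloc[0]
        assert (row["resid1"], row["resid2"], row["frequency"]) == (1, 2, 1.0)

    def test_partial_bridge_counting(self):
        series = _bridge_system(n_frames=100, with_bridge=lambda t: t < 64)
        df = water_mediated_contacts(series)
        assert df[df["cluster"] == 0]["frequency"].iloc[0] == pytest.approx(0.64)

    def test_no_waters_empty_table(self):
        c, _, _ = gen_toy_complex(ToyComplexSpec(n_waters=0, seed=0))
        series = SnapshotSeries(snapshots=[c], dt=1.0)
        assert len(water_mediated_contacts(series)) == 0

    def test_pair_counted_once_despite_many_waters(self):
        snap = make_snapshot(
            [
                ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                ("B", 2, "GLY", "CA", "C", (6.0, 0.0, 0.0)),
            ],
            waters=[(7, (3.0, 0.0, 0.0)), (8, (3.0, 1.0, 0.0))],
        )
        series = SnapshotSeries(snapshots=[snap], dt=1.0)
        df = water_mediated_contacts(series)
        assert len(df) == 1 and df["frequency"].iloc[0] == 1.0

    def test_matches_brute_force_triplets(self, toy_complex):
        snap, _, _ = toy_complex
        series = SnapshotSeries(snapshots=[snap], dt=1.0)
        df = water_mediated_contacts(series)
        got = {
            ((r["chain1"], r["resid1"]), (r["chain2"], r["resid2"]))
            for _, r in df.iterrows()
        }
        expected = set()
        for w in range(snap.n_waters):
            wx = snap.water_xyz[w]
            near_a = {
                ("A", int(snap.residue_index[i]))
                for i in np.flatnonzero(snap.chain_mask("A"))
                if np.linalg.norm(snap.xyz[i] - wx) < 4.0
            }
            near_b = {
                ("B", int(snap.residue_index[i]))
                for i in np.flatnonzero(snap.chain_mask("B"))
                if np.linalg.norm(snap.xyz[i] - wx) < 4.0
            }
            expected |= {(a, b) for a in near_a for b in near_b}
        assert got == expected

    def test_per_cluster_frequencies(self):
        series = _bridge_system(n_frames=6, with_bridge=lambda t: t < 3)
        labels = ClusterLabels(labels=np.array([1, 1, 1, 2, 2, 2]), n_clusters=2)
        df = water_mediated_contacts(series, labels=labels)
        by = {int(r["cluster"]): r["frequency"] for _, r in df.iterrows()}
        assert by[1] == 1.0 and by[2] == 0.0 and by[0] == 0.5


class TestResidueWaterCounts:
    def test_planted_three_waters(self):
        snaps = [
            make_snapshot(
                [
                    ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                    ("B", 2, "GLY", "CA", "C", (6.0, 0.0, 0.0)),
                ],
                waters=[
                    (1, (3.0, 0.0, 0.0)),
                    (2, (3.0, 1.0, 0.0)),
                    (3, (3.0, -1.0, 0.0)),
                    (4, (30.0, 0.0, 0.0)),  # far away, never interfacial
                ],
                time=float(t),
            )
            for t in range(4)
        ]
        series = SnapshotSeries(snapshots=snaps, dt=1.0)
        df = residue_water_contact_counts(series)
        a_rows = df[(df["chain"] == "A") & (df["cluster"] == 0)]
        assert a_rows["mean"].iloc[0] == 3.0
        assert a_rows["median"].iloc[0] == 3.0
        assert not a_rows["variable"].iloc[0]  # constant counts → no flag

    def test_residue_far_from_waters_all_zero(self, toy_complex):
        snap, _, _ = toy_complex
        far = make_snapshot(
            [
                ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                ("B", 2, "GLY", "CA", "C", (6.0, 0.0, 0.0)),
                ("A", 3, "ALA", "CA", "C", (0.0, 500.0, 0.0)),
            ],
            waters=[(1, (3.0, 0.0, 0.0))],
        )
        series = SnapshotSeries(snapshots=[far], dt=1.0)
        df = residue_water_contact_counts(series)
        row = df[(df["resid"] == 3) & (df["cluster"] == 0)]
        assert row["mean"].iloc[0] == 0.0
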