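"""Pipeline orchestration: run the full interface-dynamics analysis.

Stages (each skippable, later stages name their missing prerequisites):
``contacts`` → ``geometry`` → ``clustering`` → ``substates`` →
``water`` → ``stats``.  Inputs come either from structure/trajectory
files or from the built-in synthetic toy-complex generator; every
output is a CSV/JSON file in the run directory, listed in a MANIFEST,
and runs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as icl
from . import contacts as ict
from . import geometry as geo
from . import io as iio
from . import stats as ist
from . import substates as isub
from . import synthetic as isyn
from . import water as iwa
from .snapshots import SnapshotSeries

__all__ = ["run_pipeline", "load_config", "DEFAULT_STAGES"]

DEFAULT_STAGES = ["contacts", "geometry", "clustering", "substates", "water", "stats"]

CUTOFFS = {
    "contact_cutoff_A": 5.0,
    "first_shell_A": iwa.FIRST_SHELL_CUTOFF,
    "second_shell_A": iwa.SECOND_SHELL_CUTOFF,
    "interfacial_water_A": iwa.INTERFACIAL_CUTOFF,
    "relative_asa_threshold_pct": 25.0,
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _load_input(config: dict) -> tuple[SnapshotSeries, SnapshotSeries | None, SnapshotSeries | None]:
    inp = config.get("input", {})
    kind = inp.get("kind", "synthetic")
    if kind == "synthetic":
        syn = inp.get("synthetic", {})
        spec = isyn.ToyComplexSpec(
            n_residues_per_chain=syn.get("n_residues_per_chain", 16),
            atoms_per_residue=syn.get("atoms_per_residue", 3),
            interface_gap=syn.get("interface_gap", 4.0),
            n_waters=syn.get("n_waters", 60),
            box=tuple(syn.get("box", (40.0, 30.0, 30.0))),
            seed=int(config.get("seed", 0)),
        )
        return isyn.gen_toy_series(
            spec,
            n_snapshots=syn.get("n_snapshots", 10),
            dt=syn.get("dt", 1.0),
        )
    if kind == "files":
        chains = inp.get("chains")
        complex_series = iio.load_series(
            inp["structure"],
            inp.get("trajectory"),
            chain_selection=tuple(chains) if chains else None,
            stride=inp.get("stride", 1.0),
        )
        free = []
        for key, src in (("unbound_a", "unbound_A"), ("unbound_b", "unbound_B")):
            sub = inp.get(key)
            free.append(
                iio.load_series(
                    sub["structure"],
                    sub.get("trajectory"),
                    stride=inp.get("stride", 1.0),
                    source=src,
                )
                if sub
                else None
            )
        return complex_series, free[0], free[1]
    raise ValueError(f"unknown input kind {kind!r}")


def _require(produced: dict, key: str, stage: str, upstream: str):
    if key not in produced:
        raise RuntimeError(
            f"stage {stage!r} requires the output {key!r} of stage "
            f"{upstream!r}; enable it or provide the file"
        )
    return produced[key]


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write a report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "ifdyn_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", DEFAULT_STAGES)
    seed = int(config.get("seed", 0))
    manifest: list[str] = []
    summary: dict = {"seed": seed, "stages": stages, "cutoffs": CUTOFFS}
    produced: dict = {}
    log: list[str] = [f"ifdyn run; python {sys.version.split()[0]}; seed {seed}"]
    log.append("cutoffs: " + json.dumps(CUTOFFS, sort_keys=True))

    complex_series, free_a, free_b = _load_input(config)
    summary["n_snapshots"] = len(complex_series)
    chain_pair = tuple(complex_series[0].chains()[:2])

    def emit(name: str, df, columns=None):
        iio.write_table(df, out / name, columns=columns)
        manifest.append(name)

    contact_series: list[ict.ContactSet] | None = None
    if "contacts" in stages:
        contact_series = [
            ict.compute_contacts(s, chain_pair=chain_pair) for s in complex_series
        ]
        produced["contacts"] = contact_series
        rows = []
        for cs in contact_series:
            for (c1, r1), (c2, r2) in sorted(cs.contacts):
                rows.append(
                    {
                        "time_ns": cs.time,
                        "chain1": c1, "resid1": r1,
                        "resname1": cs.resnames.get((c1, r1), ""),
                        "chain2": c2, "resid2": r2,
                        "resname2": cs.resnames.get((c2, r2), ""),
                    }
                )
        emit("contacts.csv", rows, columns=[
            "time_ns", "chain1", "resid1", "resname1", "chain2", "resid2", "resname2",
        ])
        cons = ict.conservation_series(contact_series)
        emit("conservation.csv", [
            {
                "time_ns": t, "fraction_initial": f, "n_contacts": n,
                "polar_polar": tp[0], "apolar_apolar": tp[1], "mixed": tp[2],
            }
            for t, f, n, tp in zip(
                cons.times, cons.fraction_initial, cons.n_contacts, cons.type_fractions
            )
        ])
        emit("hbonds.csv", [
            {
                "time_ns": s.time,
                "n_hbonds": ict.count_interface_hbonds(s, chain_pair=chain_pair),
            }
            for s in complex_series
        ])
        summary["n_initial_contacts"] = len(contact_series[0])

    regions = None
    if "geometry" in stages:
        rows = []
        first = complex_series[0]
        asa0 = geo.interface_asa(first, chain_pair=chain_pair)
        regions = geo.classify_regions(asa0)
        emit("regions.csv", [
            {"chain": c, "resid": r, "region": cls}
            for (c, r), cls in regions.classes.items()
        ], columns=["chain", "resid", "region"])
        for s in complex_series:
            asa = asa0 if s is first else geo.interface_asa(s, chain_pair=chain_pair)
            gd = geo.gap_descriptors(s, asa, chain_pair=chain_pair)
            rows.append(
                {
                    "time_ns": s.time,
                    "delta_asa_A2": gd.delta_asa,
                    "gap_volume_A3": gd.gap_volume,
                    "gap_index_A": gd.gap_index,
                    "irmsd_vs_t0_A": geo.interface_rmsd(first, s, chain_pair=chain_pair)
                    if gd.delta_asa > 0
                    else np.nan,
                }
            )
        emit("descriptors.csv", rows)
        produced["descriptors"] = rows
        summary["delta_asa_t0_A2"] = rows[0]["delta_asa_A2"]

    labels = None
    if "clustering" in stages:
        series = _require(produced, "contacts", "clustering", "contacts")
        jm = icl.jaccard_matrix(series)
        produced["jaccard"] = jm
        emit("jaccard.csv", pd.DataFrame(jm.values))
        k_max = int(config.get("clustering", {}).get("k_max", 6))
        recommended, diag = icl.suggest_n_clusters(jm, k_max=min(k_max, jm.n))
        emit("cluster_diagnostics.csv", diag)
        k = int(config.get("clustering", {}).get("n_clusters", recommended))
        labels = icl.cluster_interfaces(jm, k)
        produced["labels"] = labels
        emit("labels.csv", [
            {"time_ns": t, "cluster": int(lab)}
            for t, lab in zip(jm.times, labels.labels)
        ])
        iio.write_json(
            {str(c): int(i) for c, i in labels.centroids.items()},
            out / "centroids.json",
        )
        manifest.append("centroids.json")
        coords = icl.pcoa_projection(jm)
        emit("pcoa.csv", [
            {"time_ns": t, "pc1": c[0], "pc2": c[1]}
            for t, c in zip(jm.times, coords)
        ])
        summary["recommended_n_clusters"] = recommended
        summary["n_clusters"] = k

    if "substates" in stages:
        series = _require(produced, "contacts", "substates", "contacts")
        labels = _require(produced, "labels", "substates", "clustering")
        table = isub.contact_frequencies(series, labels)
        emit("frequencies.csv", table.to_frame())
        rec = isub.recurrence_index(table)
        if labels.n_clusters >= 2:
            var = isub.residue_max_variance(isub.contact_variance(table))
        else:
            var = {r: 0.0 for r in rec}
        scores = pd.DataFrame(
            [
                {
                    "chain": r[0], "resid": r[1],
                    "recurrence_index": rec[r],
                    "max_variance": var.get(r, 0.0),
                }
                for r in sorted(rec)
            ]
        )
        mut_path = config.get("mutations")
        if mut_path:
            mt = isub.MutationTable.from_csv(mut_path)
            scores, unmatched = isub.hotspot_crossref(rec, var, mt)
            if unmatched:
                log.append(f"unmatched mutation residues: {unmatched}")
        emit("residue_scores.csv", scores)
        summary["n_scored_residues"] = len(scores)

    if "water" in stages:
        emit("shells.csv", [
            {
                "time_ns": s.time,
                "n_first": (sc := iwa.shell_counts(s)).n_first_shell,
                "n_second": sc.n_second_shell,
            }
            for s in complex_series
        ])
        emit("interfacial_waters.csv", [
            {"time_ns": s.time, "water_id": w}
            for s in complex_series
            for w in sorted(iwa.interfacial_waters(s, chain_pair=chain_pair))
        ], columns=["time_ns", "water_id"])
        bridges = iwa.water_mediated_contacts(
            complex_series, labels=labels, chain_pair=chain_pair, regions=regions
        )
        emit("bridges.csv", bridges)
        if free_a is not None and free_b is not None:
            n_rel, se = iwa.released_waters(complex_series, free_a, free_b, "first")
            summary["released_waters_first_shell"] = {"value": n_rel, "se": se}

    if "stats" in stages:
        aff_path = config.get("affinity_table")
        if aff_path:
            aff = pd.read_csv(aff_path)
        else:
            # synthetic affinity dataset exercising the correlation stage
            x, y = isyn.gen_correlated_pairs(
                config.get("stats", {}).get("n_complexes", 8), -0.9, seed
            )
            _, z = isyn.gen_correlated_pairs(len(x), -0.7, seed + 1)
            aff = pd.DataFrame(
                {"dg_bind": x, "n_released": y, "delta_asa": z}
            )
        res: dict = {}
        r1 = ist.pearson(aff["n_released"], aff["dg_bind"])
        res["released_vs_affinity"] = {"rho": r1.rho, "p": r1.p_value, "n": r1.n}
        if "delta_asa" in aff.columns:
            r2 = ist.pearson(aff["delta_asa"], aff["dg_bind"])
            r3 = ist.pearson(aff["delta_asa"], aff["n_released"])
            dc = ist.dunn_clark_test(r1.rho, r2.rho, r3.rho, len(aff))
            res["dasa_vs_affinity"] = {"rho": r2.rho, "p": r2.p_value, "n": r2.n}
            res["dunn_clark"] = {"z": dc.z, "p": dc.p_value}
        iio.write_json(res, out / "correlations.json")
        manifest.append("correlations.json")
        summary["correlations"] = res

    iio.write_json(summary, out / "summary.json")
    manifest.append("summary.json")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    manifest.append("run.log")
    iio.write_json(sorted(manifest), out / "MANIFEST.json")
    return summary
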