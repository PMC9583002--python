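# ifdyn — interface dynamics of protein–protein complexes

`ifdyn` analyses the interface of a two-chain protein complex along a
molecular-dynamics trajectory sampled into snapshots (typically one per
nanosecond). It is aimed at structural bioinformaticians who want to go
beyond a single crystal structure and ask: *which contacts define the
interface, how stable are they, does the interface switch between
long-lived substates, and what do the interfacial waters do?*

## What it computes

**Contacts and conservation.** A contact is a residue pair, one per
chain, with any heavy-atom distance ≤ 5 Å. Per snapshot the package
reports the contact set, the fraction of the initial contacts retained,
the polar/apolar composition of the contacts, and a geometric
cross-chain hydrogen-bond count (donor–acceptor ≤ 3.5 Å, H–D–A ≤ 30°
when hydrogens are present).

**Surface geometry.** Solvent-accessible surface areas (Shrake–Rupley,
probe 1.4 Å) give the buried surface

    ΔASA = ASA_A + ASA_B − ASA_AB ,

Levy's support/core/rim interface regions (relative-ASA threshold 25%),
the gap index `2·V_gap / ΔASA` (with the gap volume from a documented
grid approximation of the interstitial space), and the CAPRI-style
interface RMSD after Kabsch superposition of the interface backbone.

**Substate clustering.** Snapshots are compared through the Jaccard
index of their contact sets, `J(C1,C2) = |C1∩C2| / |C1∪C2|`;
hierarchical Ward.D2 clustering of the `1−J` dissimilarity partitions
the trajectory into substates. Diagnostics (smallest/largest cluster,
number of label changes in time, within-cluster dissimilarity) guide
the choice of the substate count; each substate gets a centroid
snapshot (highest mean similarity to its cluster) and a 2-D principal-
coordinates projection.

**Per-substate contact statistics.** Each contact has a relative
frequency per cluster, `F_c(XY)`. Residue-level summaries are the
maximum across-partner variance of these frequencies,
`var(X) = max_Y var_c(F_c(XY))`, and the recurrence index
`min_c max_Y F_c(XY)`, which is high exactly for residues engaged at
the interface in every substate. Experimental hotspots (single
mutations with ΔΔG < −2 kcal/mol, SKEMPI-style table) can be joined on.

**Structural waters.** Hydration shells count waters by their minimal
oxygen–heavy-atom distance (first shell < 3.4 Å, second 3.4–5.0 Å);
released waters upon complexation are
`⟨N_free A⟩ + ⟨N_free B⟩ − ⟨N_complex⟩`. Interfacial waters lie within
4 Å of both chains; a water simultaneously within 4 Å of a residue of
each chain defines a water-mediated contact for the pair.

**Statistics.** Pearson correlations and the Dunn–Clark z-test for
comparing two dependent, overlapping correlations (e.g. released
waters vs ΔASA as predictors of binding affinity measured on the same
complexes).

A synthetic-data module generates all inputs needed to exercise the
pipeline without trajectories: pseudo-atomic two-chain complexes with
explicit waters (bound and unbound), contact-set series with hidden
Markov-style substates and flip noise, and correlated sample pairs.

## Worked example

```python
from ifdyn.pipeline import run_pipeline

summary = run_pipeline({"seed": 1, "output_dir": "demo_run"})
```

runs every stage on the built-in synthetic complex (two 16-residue
chains, 60 waters, 10 snapshots) and writes the tables
(`contacts.csv`, `descriptors.csv`, `labels.csv`, `frequencies.csv`,
`shells.csv`, `bridges.csv`, …) plus `summary.json`:

```json
{
  "n_snapshots": 10,
  "n_initial_contacts": 16,
  "delta_asa_t0_A2": 739.68,
  "recommended_n_clusters": 2,
  "released_waters_first_shell": {"value": 0.80, "se": 0.91},
  "correlations": {
    "released_vs_affinity": {"rho": -0.961, "p": 0.00014, "n": 8},
    "dasa_vs_affinity":     {"rho": -0.742, "p": 0.035,   "n": 8},
    "dunn_clark":           {"z": -2.240,   "p": 0.025}
  }
}
```

Reading the output: the toy complex buries ≈ 740 Å² of surface; its 16
initial contacts fluctuate enough under thermal jitter for the
diagnostics to suggest two substates; on average 0.8 first-shell waters
are released upon binding (small, as the toy interface is narrow); and
on the synthetic affinity dataset the released-water count correlates
more strongly with the binding free energy than the interface size
does, the difference being significant per the Dunn–Clark test.

The same pipeline runs from the command line:

```sh
ifdyn run --config config.yaml --out run_dir
ifdyn contacts --config config.yaml   # single stage (+ dependencies)
```

where the YAML config names the input (`kind: files` with a
structure/trajectory and two chain labels, or `kind: synthetic`), the
stages to run, and a seed. File input accepts single- and multi-model
PDB or a GRO/PDB topology with an XTC/DCD trajectory (pre-imaged,
chains whole).

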