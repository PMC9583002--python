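# Methods

This note documents the models, conventions and numerical choices
behind `ifdyn`, and what the synthetic-data tests do and do not show.

## Snapshot model and input conventions

The unit of analysis is a snapshot: the heavy atoms of two protein
chains plus the oxygen positions of the surrounding waters at one time
point, in Å. Hydrogens, when present in the source, are kept in a
separate field and used only for hydrogen-bond angles. Waters are
recognised by residue name (HOH/WAT/SOL/TIP3/TIP, case-insensitive);
ions are discarded. Residue indices follow the source file's author
numbering with no renumbering. Parsing is delegated to MDAnalysis
(PDB single/multi-model; GRO/PDB topology with XTC/DCD trajectories).

Periodic-boundary re-imaging is assumed done upstream: chains must be
whole and the complex assembled in one image. The loader does not
attempt to fix split molecules, and distances are plain Euclidean.
Striding uses nearest-frame selection when the frame spacing does not
divide the requested interval; multi-model PDB files carry no reliable
time axis, so models are spaced `frame_dt` (default 1 ns) apart.

## Contacts

A contact is a cross-chain residue pair whose closest heavy atoms are
within the cutoff, boundary inclusive (≤ 5.0 Å by default). Contact
conservation is `|C_t ∩ C_ref| / |C_ref|` against a configurable
reference snapshot (default: the first). Contact typing uses a
configurable polarity alphabet; the default calls ARG, LYS, HIS, ASP,
GLU, ASN, GLN, SER, THR, TYR, TRP and CYS polar and the remaining
eight standard residues apolar. This partition is a package choice —
different groupings move the polar/apolar/mixed fractions, which is
why the alphabet is exposed as an argument.

Interface hydrogen bonds are counted geometrically from fixed
donor/acceptor templates for the 20 standard residues (backbone N
donates except proline, backbone O accepts, plus the usual side-chain
N/O/S sites): a cross-chain donor–acceptor pair within 3.5 Å counts,
and when explicit hydrogens exist the H–D–A angle must also be ≤ 30°.
These are the common defaults of trajectory H-bond tools; the count is
a re-implementation, not bit-compatible with any particular engine.

## Surface areas and regions

ASA uses an in-package Shrake–Rupley quadrature with a deterministic
golden-spiral point set (default 960 points per atom) and a 1.4 Å
probe. Van der Waals radii follow the Chothia protein set (carbonyl
and carboxyl carbons 1.76 Å, other carbons 1.87 Å, N 1.65 Å, O 1.40 Å,
S 1.85 Å); relative ASA normalises by Gly-X-Gly maximal exposures
(Tien et al. 2013 theoretical values). Against an analytic sphere the
quadrature is exact to < 0.1% at 960 points; against an independent
implementation (biotite) with identical radii, totals agree to ~0.2%.
Results differ from NACCESS by a few percent because of the point set
and reference tables; comparisons with NACCESS-derived numbers should
allow ±5%.

ΔASA = ASA_A + ASA_B − ASA_AB is clipped at zero within a 1 Å²
tolerance (quadrature noise on non-touching chains); a more negative
value raises, since it signals inconsistent inputs.

Interface regions use Levy's strict inequalities at the 25% relative-
ASA threshold: a residue is part of the interface when it loses more
than 0.1 Å² of ASA upon binding (the margin suppresses quadrature
noise); *support* if its relative ASA in the isolated chain is < 25%,
*core* if > 25% isolated and < 25% in the complex, *rim* if > 25% in
the complex. Interface residues failing all three strict tests (exact
boundary ties) are assigned to rim as the peripheral catch-all.
Because the quadrature grid is fixed in the lab frame, a residue
sitting within noise of the threshold can change class under a global
rigid motion; the classes are otherwise rigid-motion invariant.

## Gap volume and gap index

The gap volume is a documented grid approximation of the interstitial
space between the chains: for every cross-chain heavy-atom pair closer
than 10 Å a trial sphere is placed at the pair midpoint and shrunk
until it touches the nearest van der Waals surface; spheres with final
radius in [1.0, 5.0] Å are kept, and the volume of their union is
integrated on a 0.8 Å cubic grid. On a planted spherical cavity of
radius 3 Å the approximation recovers the analytic volume within ~1%.
Bit-compatibility with SURFNET is explicitly not claimed; the radius
bounds and grid spacing are exposed parameters. The gap index is
`2·V_gap / ΔASA` and is reported as missing when ΔASA = 0.

## Interface RMSD

The interface set is CAPRI-style: residues of either chain with any
heavy atom within 10 Å of the other chain, evaluated on a reference
snapshot (default: the first production snapshot; configurable). The
backbone (N, CA, C, O) of that fixed set is superposed by the Kabsch
algorithm and the RMSD taken over the same atoms. Using a fixed
reference set makes iRMSD(a,b) symmetric to numerical precision.

## Substate clustering

Snapshot similarity is the Jaccard index of contact sets; two empty
interfaces compare as identical (J = 1) by default, with the opposite
convention available. Clustering applies the Ward.D2 Lance–Williams
recurrence to the 1−J dissimilarities via scipy's ward linkage (the
same recurrence as R's `hclust ward.D2`, verified against a
brute-force implementation to 1e-9 on small instances). Ward on a
non-Euclidean dissimilarity is a pragmatic, field-standard choice;
merge heights are then heuristic rather than variance decompositions.
Cluster ids are renumbered by first appearance in time, and dendrogram
ties break deterministically (lowest indices first), so runs are
reproducible.

The substate count is chosen by diagnostics rather than a generic
index: for each k the table reports the smallest and largest cluster
size, the number of label changes along the trajectory and the mean
within-cluster dissimilarity (the package's concrete reading of
"intra-cluster variance", since several definitions exist). The
recommended k is the largest one whose smallest cluster holds ≥ 5% of
snapshots and whose label sequence changes at most 2·(k−1) times —
i.e. every substate is well populated and long-lived. Both thresholds
are configurable; they encode a qualitative criterion and should be
inspected, not trusted blindly, on real data.

Centroids maximise mean within-cluster Jaccard similarity (ties to the
earliest time). The 2-D projection is classical metric MDS (principal
coordinates) of 1−J: double-centred squared distances,
eigendecomposition, coordinates scaled by √eigenvalue, negative
eigenvalues truncated.

## Per-substate statistics

Contact frequencies are per-cluster proportions of snapshots showing
the contact. The across-cluster variance is the population
(divide-by-N_c) variance, keeping the maximum at 0.25 for frequencies
in [0,1] and suiting the 2–4 cluster regime; residue-level scores are
the max over partners (variance) and min over clusters of the max over
partners (recurrence). A residue without any contact in some cluster
has an empty inner maximum there and receives recurrence 0, consistent
with the index's purpose of penalising absence. Both scores are
invariant to cluster relabelling.

Hotspot cross-referencing flags residues where any single-point
mutation has ΔΔG < −2.0 kcal/mol, the inequality as printed in the
source convention for the benchmark data; tables using the common
destabilising-positive convention can set `flip_sign=True`. Multiple
mutations are dropped on load.

## Water analyses

All water distances are oxygen-to-heavy-atom minima. Shell boundaries
are half-open exactly as defined: first shell d < 3.4 Å, second
3.4 ≤ d < 5.0 Å, so no water is double-counted. The shell cutoffs are
fixed constants derived from the solvent radial structure; a distance
histogram is available through `water_min_distances` for users who
want to re-derive them for a different water model.

Released waters combine the three simulations as
`⟨N_free A⟩ + ⟨N_free B⟩ − ⟨N_complex⟩` with time averaging per series
and standard errors combined in quadrature — the only combination that
yields a per-complex scalar measuring release upon complexation.

Interfacial waters are strictly within 4.0 Å of heavy atoms of both
chains. A water-mediated contact is a residue pair (one per chain)
simultaneously within 4 Å of one water; the pair counts once per
snapshot however many waters bridge it, and the bridging water
identity may change freely between snapshots — water residence times
and exchange dynamics are out of scope. Per-residue interfacial-water
contact counts are summarised per cluster by quartiles, with residues
whose counts vary strongly (std > 2 over the trajectory) flagged.

## Correlation statistics

Pearson correlation uses scipy. The Dunn–Clark (1969) test compares
two dependent overlapping correlations r12 and r13 sharing variable 1:
both are Fisher-transformed and the z statistic divides their
difference by √(2(1−c)/(n−3)), where c is the covariance correction
computed from r23. Monte-Carlo calibration under a trivariate-normal
null (n = 50, 2000 replicates) keeps the empirical type-I error within
[0.03, 0.07] at α = 0.05, which the test suite asserts. No
multiple-testing correction is applied by default (raw p-values are
reported); Benjamini–Hochberg can be applied downstream.

## Synthetic data: what it shows and what it does not

The toy complex is two lattices of rigid three-atom pseudo-residues
facing across a configurable interface gap, with waters
rejection-sampled uniformly in a box at ≥ 2.4 Å from any heavy atom
and from each other (≈ van der Waals contact minus overlap). Residue
names are drawn from the standard alphabet so polarity typing, ASA
references and H-bond templates all operate. Pseudo-trajectories add
isotropic Gaussian coordinate jitter and re-sample waters per frame.

The contact-series generator switches between predefined substate
contact sets along prescribed dwell segments and flips each contact of
a finite universe (union of substate sets plus a decoy pool)
independently with a given probability. Default test conditions use
two substates of 150 snapshots each with 5% flip noise — substate
dwell times and sampling density comparable to a several-hundred-
nanosecond trajectory sampled at 1 ns.

Passing tests on these generators demonstrates algorithmic
correctness: contacts, shells, bridges and frequencies equal
brute-force enumeration; clustering recovers planted substates;
estimators hit analytic values. They do not demonstrate that a real
force field produces such substates, nor calibrate cutoffs for a
specific water model, nor validate the ASA tables against experiment —
those are properties of the input trajectories, not of the code.

## Degenerate inputs and tie rules

* Empty reference contact set → conservation undefined, error.
* Empty ∩ empty Jaccard = 1 (configurable to 0).
* ΔASA = 0 → gap index reported as missing, not 0.
* Exactly-25% relative ASA → rim (strict inequalities, catch-all).
* Centroid ties → earliest snapshot; dendrogram ties → lowest indices.
* Zero waters → all water analyses return zeros/empty tables.

## Problem sizes

The bundled runs use deliberately small systems: toy complexes of
2 × 16 three-atom residues with 40–60 waters and 6–10 snapshots, and
contact series of up to 300 snapshots. These sizes exercise every code
path while keeping the full suite around ten seconds; all operations
scale to real systems (hundreds of residues, thousands of waters,
hundreds of snapshots) through the KD-tree neighbour searches used
throughout.

## Known limitations

* ASA and gap volume are grid/quadrature approximations: a few percent
  from NACCESS/SURFNET, adequate for trends and classifications.
* Ward.D2 on Jaccard distances inherits the usual caveat that the
  dissimilarity is non-Euclidean.
* No periodic-boundary handling; inputs must be pre-imaged.
* Water dynamics (residence, exchange kinetics) are out of scope.
* The hotspot ΔΔG inequality follows the benchmark's printed
  convention, which is the opposite sign of several mutation
  databases; the flag to flip it is deliberate rather than silent.
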