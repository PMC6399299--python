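# Methods

## Problem setting

`pocketscreen` implements a structure-based drug-repurposing screen: given
a query drug-binding pocket (the motivating case is the taxane site on
beta-tubulin), find other protein–ligand pockets whose physicochemical
microenvironments are similar enough that their cognate ligands are
candidate binders of the query site. The package also quantifies the
downstream validation assays used to test such predictions: in vitro
tubulin polymerization kinetics, microtubule phenotype scoring, and
live-cell potency estimation.

## Pocket definition

A pocket is the set of polymer residues with at least one heavy atom
within **6.0 Å (inclusive)** of any heavy atom of the bound ligand.
Hydrogens are ignored on both sides because their presence in deposited
structures is inconsistent. Only the first coordinate model is used;
alternate locations collapse to the highest-occupancy conformer
(lexicographically smallest altloc id on ties). Waters, common ions and a
short list of crystallization additives are excluded both as candidate
ligands and as pocket members. Residues from any chain may belong to a
pocket (binding sites can span subunit interfaces, as the taxane site
illustrates); no symmetry-mate expansion is performed, so pockets formed
by crystallographic neighbors are not reconstructed. Membership exactly at
the 6.0 Å boundary is a knife edge: it is exact for as-given coordinates
but can flip under floating-point recoordinatization (e.g. rotation of the
whole structure).

## Microenvironment featurization

Each pocket residue is summarized by the heavy atoms surrounding its
**side-chain centroid** (CA for glycine or when no side-chain atom is
resolved; all-heavy-atom centroid as a last resort). The surroundings are
partitioned into six concentric shells of width 1.0 Å — shell *k* covers
(k−1) < d ≤ k — and each shell contributes 80 non-negative count-style
descriptors, giving the 480-length vector per residue. The descriptor set
(`default-v1` schema) comprises element counts (C/N/O/S/P/other),
per-residue-type counts for the 20 standard amino acids, residue-class
counts (hydrophobic / aromatic / polar-uncharged / positive / negative /
special), backbone vs side-chain counts, hydrogen-bond donor and acceptor
heavy atoms, charged-group atoms, aromatic ring atoms, total heavy atoms,
Kyte–Doolittle hydropathy magnitudes summed in five signed bins, and a
5 × 7 element-by-class cross table. All atoms of the model contribute —
including the probe residue's own and those of other hetero groups (as
class "other") — **except the pocket's cognate ligand**, which is excluded
so that pockets remain comparable across different or absent bound
ligands. An atom exactly at the shell center (d = 0) falls in no shell.
Vectors are binarized at threshold 0 (presence/absence), which is what the
Tanimoto comparison consumes. Feature vectors carry their schema id and
cross-schema comparisons are rejected.

An alternative centering on residue-type-specific functional atoms (rather
than side-chain centroids) exists in the literature; it is noted here but
not implemented.

## Pocket similarity and the PocketFeature Score

For two pockets A and B the pairwise residue similarity is the Tanimoto
coefficient of their bit vectors, T = |A∧B| / |A∨B| (0 when both are
empty). Residues are then matched one-to-one by a maximum-weight bipartite
assignment (Hungarian algorithm, `scipy.optimize.linear_sum_assignment`)
over the Tanimoto matrix with entries below an inclusion cutoff **tau
(default 0.5)** zeroed; zeroed pairs cannot improve the objective and are
dropped from the final pairing, which makes the complete-assignment
optimum identical to the best partial matching restricted to pairs with
T ≥ tau. The **PocketFeature Score** is

    PFS(A, B) = − Σ_matched T(a, b)

so more negative means more similar, −min(|A|,|B|) ≤ PFS ≤ 0, a
self-comparison of an n-residue pocket scores exactly −n, and screening
significance uses the strict cutoff **PFS < −3.5**. Symmetry, self-
optimality and monotonicity in tau follow from the construction and are
enforced as tests, as is exact agreement with brute-force enumeration of
all matchings on matrices up to 7×7. Optional post-hoc normalizations of
PFS (by pocket size or by a background distribution) are deliberately not
applied by default; the published score's normalization is not specified,
so absolute parity with published PFS values for real PDB pockets is not
claimed.

## Library construction and docking post-processing

Drug-likeness counts violations of the four Lipinski rules (MW > 500 Da,
logP > 5, H-bond donors > 5, acceptors > 10; acceptors are supplied as
N+O counts — whether the original analysis used this or Lipinski's variant
is ambiguous, so the counts are taken as input). A compound is kept when
it has **fewer than 2 violations** and its MW lies in the **inclusive
170–1000 Da window** (the window applies in addition to the MW rule inside
the violation count). Deduplication keeps the first record per structure
key (InChIKey or equivalent); computing keys from SMILES is left to
standard cheminformatics tooling so the core is testable on plain tables.

Docking scores ΔG (kcal/mol) convert to inhibition constants via
Ki = exp(ΔG / RT) with R = 1.9872036×10⁻³ kcal K⁻¹ mol⁻¹ and T = 300 K;
log Ki is therefore linear in ΔG with slope 1/RT. High-confidence binders
require ΔG **strictly below −6 kcal/mol**. Target enrichment counts hits
per annotated target family (unannotated hits pool under "other"),
descending with alphabetical tie-break.

## Chemical similarity network

Compounds are hashed circular (Morgan) fingerprints, radius 2 over 2048
bits by default (RDKit). An undirected edge joins two compounds when their
fingerprint Tanimoto is **strictly above 0.75**. Nodes are classed by PFS:
`high_sim` below −3, `low_sim` above −2, `intermediate` for the
[−3, −2] band that the two published color rules leave open, and
`unscored` without a PFS. Outputs are GraphML plus edge-list and
node-table TSVs; layout and rendering are out of scope, and numeric Tc
parity with the original network tool (whose fingerprint is unspecified)
is not claimed.

## Assay quantification

**Polymerization.** Raw fluorescence curves from one run are normalized so
the lowest reading across all curves of the run maps to 0% and the
paclitaxel reference curve's 30-min end point to 100%; this removes
instrument gain and offset exactly. Vmax is the steepest least-squares
slope over any 3 consecutive points (%/min; the window length is this
package's choice, as none is published) and MEP is the final normalized
value. Fold changes divide a condition's statistic by the DMSO control's,
with FC > 1 on both statistics read as polymerization enhancement and
both < 1 as suppression.

**Phenotypes.** The abnormality score is total category counts divided by
cells scored; one cell may contribute to several categories, so scores can
exceed 1. The nocodazole-challenge readout is the (polymerized, soluble)
cell-fraction pair.

**Potency.** EC50 of proliferation inhibition (EC50^P) interpolates, in
log10 concentration, where the per-dose confluence regression slope
crosses half the vehicle slope; with no bracketing dose pair or a
non-positive vehicle slope the result is an explicit *not assigned* with a
diagnostic, never a silent default. EC50 of death at 24/48 h (EC50^D)
is the midpoint of a four-parameter logistic fit on log10 dose
(least squares, floor constrained to [0, 1], optimizer tolerances 1e−14);
the fit is rejected as not assigned below 4 distinct doses, on
non-convergence, or when the fitted span (ceiling − floor) is below 0.1 —
10% of the full [0, 1] dead-fraction range — which catches flat data.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions for every stage.

* **Toy complexes** plant exact nearest-heavy-atom distances: ligand atoms
  lie on the non-positive x axis with one atom at the origin, residues
  (backbone anchor + side-chain template atoms with correct elements) sit
  in a cone around +x with their anchor at the planted radius and all
  other atoms strictly farther out. Pocket residues sample 3.0–5.8 Å,
  decoys 7.5–12 Å. Perturbation adds Gaussian coordinate jitter and
  relabels a fraction of residues to random types. No stereochemistry,
  secondary structure, packing or solvent is modeled, so passing tests
  demonstrate correctness of the geometric and combinatorial rules — not
  performance on real crystal structures, where microenvironments are
  denser and more correlated.
* **Compound tables** plant exact drug-like and duplicate compositions:
  drug-like records sit inside all rule bounds (a third carry exactly one
  violation), failures are unambiguous (out-of-window MW or two
  simultaneous violations), duplicates copy an original's key and
  descriptors. Real chemical-space marginals are not emulated.
* **Polymerization runs** are logistic curves rescaled to exactly 0% at
  t=0 and their plateau at 30 min, emitted as raw AU (offset 0.05, gain
  0.01 AU/%) with Gaussian noise at 30 s sampling; the logistic rate is
  solved so the analytic maximum slope equals the planted Vmax, and the
  plateau is the planted MEP. The reference plateaus at 100% with
  Vmax 5.8 %/min and the vehicle control at 20.5% with 1.0 %/min,
  mirroring a paclitaxel/DMSO pair. Lag-phase asymmetry and plate drift
  are not modeled.
* **Live-cell series** use linear confluence growth whose slope follows a
  descending 4PL in log dose and dead fractions following an ascending 4PL
  (ceiling 0.9), default midpoint 25 µM with hill 1.5 over 8 log-spaced
  doses from 1–200 µM — a mid-range potency typical of the compounds this
  assay targets. Confluence noise 2 percentage points and dead-fraction
  noise 0.05 with two replicates are the simulated-recovery conditions.
  Death within the first frames, debris artifacts and well effects are not
  modeled.

Problem sizes throughout (10-residue pockets with 20 decoys × 20
replicate screens; 20 compound tables of 50–200 records; 20-seed potency
recoveries; 100 oracle matrices up to 7×7) are chosen so each experiment
is statistically informative while the whole suite and the acceptance
script each complete in seconds.

## Numerical choices and degenerate inputs

* Altloc ties break lexicographically; ligand enumeration orders by
  locator; screen results sort by (PFS, pocket id); enrichment ties break
  alphabetically — all outputs are deterministic.
* Tanimoto of two all-zero vectors is 0 by definition; an empty pocket
  cannot be aligned; a normalization run whose reference end point equals
  the global minimum is an error.
* All thresholds keep their published open/closed sense: pocket membership
  ≤ 6.0; significance PFS < −3.5; docking ΔG < −6; network edges
  Tc > 0.75; drug-like violations < 2 with 170 ≤ MW ≤ 1000.

## Known limitations

* The 80 per-shell descriptors are this package's fully specified
  reconstruction of a FEATURE-style count schema; the original descriptor
  list is unpublished here, so absolute PFS values for real PDB pockets
  are not comparable and are not an acceptance surface.
* Pockets are taken from the deposited asymmetric unit; biological
  assemblies and symmetry mates are not generated.
* EC50^P uses interpolation between measured doses only — it never
  extrapolates, by design, and reports *not assigned* instead.
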