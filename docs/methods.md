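# Methods

## Problem and scope

A missense mutation in a DNA- or RNA-binding protein changes the complex's
binding free energy by ΔΔG = ΔG(mutant) − ΔG(wild-type), in kcal·mol⁻¹ with
positive values destabilizing. The package estimates ΔΔG by regression and
flags "hotspot" mutations (ΔΔG ≥ 1 kcal·mol⁻¹) by classification, taking as
inputs: PDB structures of the wild-type and mutant complexes, five-term
per-residue-pair energy-decomposition tables for both states, PSI-BLAST
conservation profiles, and a mutation table. Producing the decomposition
tables (force-field minimization, generalized-Born solvation, MM/GBSA
decomposition) is deliberately outside the package: the energy engine is a
pluggable upstream producer, identified only by a GB-model tag (HCT, OBC1,
OBC2, GBn1, GBn2, or `synthetic`). Mutant model building, PSI-BLAST runs and
groove assignment are likewise external.

## Structural conventions

* Author numbering; a monomer is keyed by (chain, seq id, insertion code).
* First PDB model only; waters, ions and HETATM ligands dropped; hydrogens
  kept but excluded from all geometry; for alternate locations the
  highest-occupancy conformer is kept (ties: first encountered).
* Inter-monomer distance is the minimum over heavy-atom pairs — the same
  heavy-atom convention that underlies the interface definition, so
  distances and contacts are mutually consistent.
* Interface: every (residue, nucleotide) pair with distance strictly below
  the cutoff (default 5.0 Å). Interface membership is computed on the
  wild-type structure and reused for the mutant-state partitions, since the
  two states share numbering and the mutant geometry differs only locally.

## Energy features

Shells for the target-centred groups are half-open intervals (lo, hi]:
0 (the decomposition self entry of the target), (0,3], (3,4], (4,5], (5,6],
(6,∞) Å. Shell 0 carries the self term rather than acting as a mere marker
of the mutated position; the alternative loses the self energy entirely.
ETOR and EPP partition protein residues only; nucleotides contribute through
per-residue energies (self + all pairs) and through the interface groups.
In EINI the interface partition covers all pairs (and self entries) among
interface members; every remaining entry — including pairs that straddle the
boundary — is noninterface, so the two partitions always sum to the
whole-complex energies. In EPI, self entries join the same-kind partition
(residue self → residue–residue, nucleotide self → nucleotide–nucleotide),
which preserves EPI-sums-to-interface exactly.

Feature vectors concatenate wild-type values and mutant − wild-type
differences (5 terms per partition), giving widths EWC 10, ETOR 60, EPP 60,
EINI 20, EPI 30. The difference direction matches the ΔΔG sign convention.

The decomposition CSV dialect is
`chain_i,seq_i,icode_i,chain_j,seq_j,icode_j,total,ele,vdw,gb,sa`
(kcal·mol⁻¹), one row per unordered pair or per direction (directional rows
are summed). Term closure |total − (ele+vdw+gb+sa)| is validated with a
configurable tolerance (default 10⁻³; the five-term identity is approximate
for real engines, exact for the synthetic generator).

## Nonenergy features

**Solvent accessibility** uses a Shrake–Rupley sampler with golden-spiral
sphere points (deterministic for a fixed point count; default 960), probe
1.4 Å and united-heavy-atom radii (C 1.80, N 1.65, O 1.40, S 1.85,
P 1.90 Å). The unbound state is the protein chains extracted in place, no
re-minimization. Relative accessibility divides by reference areas from the
extended Ala-X-Ala theoretical maxima for the total category; the mainchain
reference is a residue-independent 40 Å², the sidechain reference is the
remainder, split between polar and nonpolar in proportion to the residue's
polar (N/O/S) vs nonpolar sidechain heavy-atom counts. Categories with a
zero reference (glycine sidechains) report RSA 0 by convention.

**Hydrogen bonds** are geometric: donor–acceptor ≤ 3.5 Å and, when the
donor's bonded heavy atom is resolvable (nearest heavy atom within 1.8 Å),
antecedent–donor–acceptor angle ≥ 90°; hydrogens are not required. This is
a documented approximation of HBPLUS defaults, not a re-implementation.
Donors: nitrogens plus hydroxyl oxygens; acceptors: oxygens plus
nucleobase ring nitrogens N1/N3/N7.

**Contact features** reuse the 5 Å heavy-atom cutoff (no separate value is
established for them): per target, the number of interacting partner
monomers of each kind and the atomic contacts per partner.

**Conservation** is the Jensen–Shannon divergence (base 2, mixture weight
½) between a position's weighted-observed-percentage distribution and the
BLOSUM62 background, in [0,1], higher = more conserved; no sequence window
is applied. All-zero profile rows are replaced by the background. Profile
rows map to chain residues by sequence order and must match the chain
length.

**Knowledge scores (ENDES slot).** The seven docking-derived scores are
defined externally, so the package exposes a provider slot. The built-in
provider computes three scores itself — a sidechain score (fraction of
heavy atoms in the sidechain), a residue-type interface propensity from a
built-in table, and the JSD conservation — and zero-fills the remaining
four; external providers may supply all seven. Interface (IR-) variants of
every residue-level group are exact sums over interface residues.

**Levy location classes** use a 25% relative-accessibility exposure cutoff
on the total category: interior (uRSA < 25, no burial), surface
(uRSA ≥ 25, no burial), support (uRSA < 25, buried further), rim
(uRSA ≥ 25, bRSA ≥ 25, buried), core (uRSA ≥ 25, bRSA < 25). The exact
thresholds of the original scheme are not restated in the source
literature, so they are centralized and retunable.

## Modelling

Random forests (500 trees, unlimited depth, seed 2021, one job) are the
learners; the learner family is fixed but hyperparameters were never
specified upstream, so scikit-learn defaults plus a fixed tree count are
used. Evaluation is leave-one-complex-out: one fold per complex, metrics on
the pooled out-of-fold predictions (Pearson r and RMSE for regression, MCC
at a 0.5 probability threshold and rank-based AUC for classification; the
classification threshold is a package choice). Sequential backward
selection starts from all candidate groups, removes the group whose removal
most improves the pooled LOCOV criterion (PCC for regression, AUC for
classification — the classification criterion is this package's extension),
and halts at the first non-improving round; removal ties break to the
lexicographically smallest name. The ensemble weights α (MPD energy
combination) and β (energy/nonenergy combination) take defaults 0.4 and
0.6/0.5 and can be re-searched on the 11-point grid {0.0,…,1.0}; ties break
to the smaller weight, and α is tuned before β (the two are combined
sequentially rather than jointly — a documented choice where either order
is defensible). The MPD energy combination weights model *outputs*, not
concatenated features, which empirically dominates direct integration.
Default selected groups: MPD energy {ETOR, EPI}, nonenergy {dASA, NHB,
CFAA, CFNA, IR-CFAA}; MPR energy {EWC}, nonenergy {bRSA, uRSA, dASA,
IR-dASA, NHB, ENDES, JSD}; GB tags HCT (MPD) and OBC1 (MPR).

## Synthetic data

The generator emulates the statistical structure the models assume, not
physics. Geometry: a straight idealized peptide (backbone N/CA/C/O plus
labelled sidechain pseudo-atoms sized per residue type) against a straight
idealized nucleic strand; a configured subset of residues (default 4 of 12)
sits 4 Å from paired nucleotides (inside the 5 Å rule), all others > 6 Å
away. Pair energies decay exponentially with distance (scale 3 Å), with
exact five-term closure; the mutant table adds a planted per-mutation
effect (uniform on [−1, 4] kcal·mol⁻¹) to the electrostatic term of the
target's entries, split across them by the kernel, so the whole-complex
total shifts by exactly the effect. Labels are
ΔΔG = effect + N(0, σ) with σ = 0.3 kcal·mol⁻¹ by default. Profiles are
Dirichlet rows sharpened at designated conserved (interface) positions.
The benchmark sizes — 40 complexes × 6 mutations — give 240 labelled
mutations, comparable in scale to real curated training sets, while the
per-complex sizes (12 residues, 6 nucleotides) are the smallest shapes that
exercise every feature group.

What passing tests on this generator do show: the partition accounting is
exact, the geometry matches brute force, selection discards uninformative
groups, and a planted linear energy signal is recovered through the full
file-based pipeline. What they do not show: predictive accuracy on real
complexes, which depends on the external energy engine and the curated
experimental data; the toy geometry has no helices, grooves, packing or
realistic energetics.

## Numerical choices

* Interface comparison is strict (<); shell boundaries half-open (lo, hi].
* Conservation identities hold to 10⁻⁶ kcal·mol⁻¹ on synthetic tables.
* SASA is deterministic: identical input and point count give bit-identical
  output; there is no random orientation step.
* Degenerate inputs: empty interfaces give zero partitions with a logged
  warning (not an error); residues with no contacts get zero contact
  strengths; single-class training folds predict the constant class
  probability; an all-identical pair of samples compares as p = 1.
* All pipeline randomness flows from one configured seed; repeated runs are
  byte-identical (feature matrices, reports, serialized model bundles).

## Known limitations

* No mmCIF input; PDB ATOM/HETATM only, first model.
* The hydrogen-bond and accessibility re-implementations approximate HBPLUS
  and NACCESS; absolute values differ from those programs even where trends
  agree.
* Four of the seven knowledge-based scores exist only through external
  providers.
* The trained-model defaults (group choices, α, β) are recipes taken from
  the published study; retraining them on real data requires the external
  energy engine and curated mutation sets.
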