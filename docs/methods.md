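# Methods

This note records the models, parameter choices and numerical conventions
behind `halosite`, and what the synthetic-fixture tests do and do not
establish about real crystal structures.

## Structure model and I/O

Structures are flat lists of heavy atoms with author residue numbering and
insertion codes preserved; chains and residues are derived views.  Parsing
and serialisation go through gemmi for both PDB and mmCIF.  Two policies are
applied on read:

- **Alternate locations.** One position per atom is kept — the highest
  occupancy, ties broken by alphabetically first alt-loc id.  Ion censuses
  count one position per atom, so retaining multiple partial positions would
  double-count ligands.
- **Hydrogens** are dropped.  All geometric analyses here are heavy-atom
  analyses, and crystallographic depositions at the relevant resolutions are
  heavy-atom models.

Monatomic-ion residues named K, NA, MG, CL, CA map directly to their
elements (PDB convention) when a file lacks element columns.

Coordinates are orthogonal Å everywhere; fractional coordinates exist only
inside the crystallographic module.

## Crystal symmetry and packing context

Symmetry operators come from the file; a built-in table covers P1 and P2₁
for files without operator records (the space groups of the structures this
package was built around).  Expansion enumerates every (operator, lattice
translation) placement within ±2 unit cells and keeps copies approaching the
deposited atoms within a caller-supplied radius.  Neighbor search is an
exact k-d–tree query (scipy `cKDTree`) with an explicit distance-then-serial
sort, and is verified against an all-pairs brute-force oracle; the tree is
an implementation detail, the contract is "exactly the atoms within r".

**Crystal-contact radius: 4.0 Å** (configurable, echoed in every report).  A
site is a lattice artefact candidate when any symmetry-copy atom lies within
this distance of the ion or one of its ligands, or when a ligand itself
carries symmetry-copy provenance.  4.0 Å sits just beyond coordination
distance, so it catches sites whose shell is completed — or whose formation
is blocked — by a packing neighbour without sweeping in the bulk lattice.
No published criterion pins this number; it is this package's definition.

## Ion coordination shells

First-shell cutoffs (ion centre to coordinating atom, configurable):

| species | cutoff | coordinating atoms |
|---------|--------|--------------------|
| K⁺      | 3.5 Å  | O |
| Na⁺     | 3.1 Å  | O |
| Mg²⁺    | 2.6 Å  | O |
| Cl⁻     | 3.8 Å  | N, O |

These are standard ion–oxygen coordination ranges; typical observed K–O
contacts fall at 2.7–3.2 Å, so 3.5 Å closes the first shell without reaching
into the second.  Cutoffs above 6 Å are rejected as unphysical.  Counting is
cutoff-sensitive at the margin: when a census is used comparatively, the
per-contact distance table lets the effective cutoff be documented and swept.

Ligand chemistry is a (residue, atom-name) lookup: backbone O →
main-chain carbonyl; Asp OD1/OD2, Glu OE1/OE2 and terminal OXT →
carboxylate; Ser OG, Thr OG1, Tyr OH → hydroxyl; Asn OD1, Gln OE1 → amide;
HOH O → water; any hetero-compound oxygen → hetero.  Unknown pairs classify
as OTHER with a warning, never silently.  "Protein ligands" in censuses are
the four polymer oxygen classes; waters and hetero oxygens are tallied
separately.  Other ions inside a cutoff are recorded as neighbours, not
ligands — necessary for architectures where a cation bridges two hydrated
cations across a packing interface.

Site equivalence across crystallographically independent chains: each site
is assigned to the chain providing most of its protein ligands, mapped into
a reference chain's frame by Cα superposition, and single-linkage clustered
with a 2.5 Å merge radius.  Classes are numbered by descending multiplicity,
ties by lowest contacting residue number then ion serial — deterministic
output ordering.

Mg²⁺ geometry: the octahedral score is the mean absolute deviation of
ligand–Mg–ligand angles from the nearest ideal angle (90°/180°); carboxylate
linkage is *direct* when a carboxylate O is in the first shell, and
*water-mediated* when a first-shell water O lies within hydrogen-bond range
(2.4–3.2 Å) of a carboxylate O.

## Surface composition

SASA is Shrake–Rupley sphere sampling with a deterministic golden-section
spiral lattice (default 960 points/atom) — no randomness, bit-stable
results.  Radii are a single pinned Chothia-style set (C 1.87, N 1.65,
O 1.40, S 1.85 Å), reported in the output header; published SASA programs
differ in their radii, so reproducibility requires pinning one set.
Quadrature is exact for an isolated atom and orientation error at the
default density is a few tenths of a percent of the total (well under 0.1%
at 4000 points).

Miller classes: nonpolar = all C and S; charged = Asp/Glu carboxylate O,
Lys NZ, Arg NE/NH1/NH2, terminal OXT; polar = remaining N/O.  His side-chain
N is polar, not charged, following the original convention (switchable in
code).  Composition analysis requires a protein-only model — solvent, ions,
cofactors and expression-tag residues must be stripped first — and refuses
atoms it cannot classify rather than skewing fractions silently.

The halophilic fingerprint metrics are residue fractions (Asp+Glu)/N, Lys/N,
Thr/N, Phe/N plus the charged/polar/nonpolar surface fractions; reference
sets are recomputed with the same code and radii rather than imported from
published tables, so query and reference are always commensurable.
`compare_profiles` reports per-metric reference mean, SD, z-score and rank.

## Water structure

The hydrogen-bond network joins water oxygens 2.4–3.2 Å apart.  A
"pentagonal array" is operationalised as a **chordless** 5-cycle whose
vertices deviate from their best-fit plane by at most **0.5 Å**.  The
literature reports such arrays by inspection without a formal criterion;
both parameters here are explicit, configurable and echoed in the output, so
a zero-count result is always relative to a stated definition.  Ring search
is bounded depth-first enumeration on the sparse network (water H-bond
graphs have low degree), verified against exhaustive 5-subset enumeration.

The waters-per-residue statistic divides modelled waters by modelled polymer
residues; it is resolution-dependent in real data and is reported as a
descriptive number, not a normalised one.

## Domain rotations

Hinge rotations are measured the way dynamic-domain programs report them:
superpose the two conformers on the core domain (Cα only, Kabsch with a
proper-rotation guarantee), then decompose the residual rigid transform of
the mobile domain into screw parameters and report the rotation angle to
0.1°.  Cα-only fitting is robust to side-chain disorder in weakly ordered
mobile domains.  Domain boundaries are user input — automatic segmentation
is out of scope — with the two-domain dehydrogenase split shipped as the
default (d1: 1–92 ∪ 283–308; d2: 93–282; hinges 89–92, 277–282).  Because
segmentation differs between programs, agreement with published DynDom
angles is expected only within ~±2°; missing residues are dropped pairwise
and an error is raised if fewer than half a domain's residues pair.

## Kinetics and stability

Michaelis–Menten fitting is nonlinear least squares on v = V_max·S/(K_M+S),
initialised from a Hanes–Woolf linearisation and computed on the
max-normalised rate scale so the fit is exactly equivariant under rescaling
of v.  Standard errors come from the fit covariance.  Data with no curvature
(v ∝ S) or non-positive optima raise errors rather than returning garbage.

Turnover arithmetic: k_cat [min⁻¹] = V_max [U/mg] × subunit mass [Da] ×
10⁻³; efficiency = k_cat/K_M [mM⁻¹·min⁻¹], rounded to the nearest integer
when reported in tabulated form.  The default subunit mass is **33,200 Da**,
back-solved from the tabulated V_max/k_cat pairs of the ~66 kDa homodimeric
enzyme this package was built around (the rows imply 33.2–33.9 kDa and no
exact mass is published); it is always an explicit parameter, and k_cat is
therefore treated as mass-conditional.  One tabulated efficiency (83/0.014)
prints as 5928 where nearest-integer arithmetic gives 5929; the package
reports 5929 — rounding is never bent to match a likely truncation.

T_m is the midpoint of a fitted Boltzmann sigmoid
F = F_lo + (F_hi − F_lo)/(1 + exp((T_m − T)/s)); if the sigmoid fails, the
fallback is the argmax of dF/dT after a 5-point moving average, and the
method used is recorded.  The fit is invariant under affine transforms of
the fluorescence axis, and flat or strictly linear curves raise a
no-transition error.

## Synthetic ground truth

The generator builds ideal α-helices (φ = −57°, ψ = −47°, standard bond
geometry; consecutive backbone carbonyl O ~3.3 Å apart, i.e. within
K⁺-bridging range) and plants coordination shells with exactly known
composition: K⁺ sites receive four oriented glycine peptide units (carbonyl
O pointing at the ion) plus waters, at K–O distances drawn from 2.70–2.90 Å;
Mg(H₂O)₆ sites are exact octahedra at 2.05–2.15 Å.  Planted distances live
well inside the detection cutoffs, so recovery tests cannot flake on
borderline contacts.  Crystal contacts are engineered by fixing the cell
a-axis so a marker atom's +a lattice copy lands 3.8 Å from a planted ion —
inside the 4.0 Å context radius, outside the 3.5 Å coordination cutoff.
Every generator is bit-reproducible from (parameters, seed) with no hidden
global state.

What passing on this ground truth shows: the detection, classification,
bridging, clustering, context and ring machinery is exact when geometry is
clean and shells are unambiguous.  What it does not show: robustness to the
messiness of real depositions — partial occupancy, alternate conformations
beyond the documented policy, misassigned ion identities, unmodelled
solvent, or censuses counted at a different effective cutoff than the
original analysis.  The accession-dependent tests exist precisely to cover
that gap and run whenever the deposited files are supplied locally.

Problem sizes used by the acceptance script: 20 composite toy crystals
(4 K⁺ + 2 Mg²⁺ sites and one planted pentagon each), 200 noisy kinetic
replicates at 5% noise, one 147-point melt curve at 2% noise — enough for
stable rates and medians while keeping the whole run in seconds.

## Known limitations

- Space-group support beyond operators present in the file covers only P1
  and P2₁; no full International Tables library.
- Lattice translations are searched within ±2 cells; pathological needle
  cells could in principle need more.
- No bond-valence ion identification: ion identities are taken from the
  deposited model.
- Water-ring search assumes waters are single oxygens (no explicit H
  orientation).
- The Miller table covers standard amino-acid atoms; modified residues must
  be stripped or will raise.
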