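# Methods

This note records the models, parameter choices and numerical decisions
behind `posetriage`, and what the synthetic-data tests do and do not
demonstrate about real docking data.

## Scaffold clustering

**Model.** Ligands sharing a scaffold are assumed to express a common
binding orientation through the scaffold's placement in the receptor frame.
The distance between two poses is the in-place RMSD over the scaffold's
heavy atoms — deliberately *without* Kabsch superposition, because docking
poses already share the receptor frame and superposition would erase exactly
the positional signal (two spatially distinct modes with identical internal
conformations would collapse to zero distance). The RMSD is minimised over
the scaffold's graph automorphisms (phenyl two-fold flip, carboxylate oxygen
swap; 4 for the phenylalanine core) so that chemically equivalent atom
numberings cannot inflate distances.

**Clustering.** Complete-linkage agglomeration, cut at height *h*: clusters
are the maximal merge-tree nodes with cophenetic distance ≤ *h*. Complete
linkage is the right functional here because its merge criterion bounds the
cluster *diameter*, matching the "all poses within ~*h* of each other"
reading of a consensus mode, and it cannot chain through bridging poses the
way single linkage does. Ties between equal-linkage merges are broken toward
the lexicographically smallest pair of current cluster indices, which makes
the dendrogram deterministic across platforms. The implementation is a
Lance–Williams update (`new_row = max(row_a, row_b)`); the test suite pins
it against a from-scratch O(n³) agglomerative oracle on 200 random
matrices and against an independent hierarchical-clustering library.

**Defaults.** Height 2.0 Å; a cluster is a common scaffold cluster (CSC)
when it contains poses of at least 6 of the 8 docked ligands. All cutoffs in
the package are inclusive (≤ / ≥) except the halogen-bond criteria, which
are strict as printed conventionally (below).

## Interaction fingerprints

The binding-site universe of a pose is every residue with a heavy atom
within 5.0 Å of a ligand heavy atom. Two bit classes per residue:

* **Hydrogen bond** (directional, ligand-donates vs ligand-accepts):
  D···A ≤ 3.5 Å and, when the donor hydrogen is explicit, best
  ∠D–H···A ≥ 120°. Without hydrogens the fallback requires every heavy
  neighbour R of the donor to satisfy ∠R–D···A ≥ 90°, which rejects
  contacts buried behind the donor. These are conventional crystallographic
  criteria; docking outputs vary in whether they carry hydrogens, so both
  paths are first-class.
* **Hydrophobic**: any apolar-heavy-atom pair ≤ 4.5 Å, aggregated to one
  bit per residue (occupancy statistics are reported per residue, not per
  atom pair).

Atom typing is force-field-free and a pure function of graph + elements:
donors are N/O bearing ≥ 1 H; acceptors are N/O with a lone pair (quaternary
or positively charged N and amide N excluded); hydrophobic atoms are C/S
with no attached N/O/F and no formal charge, plus all halogens — halogens
deliberately play a dual hydrophobic/σ-hole role; cationic centres are
N with formal charge +1 or primary aliphatic amines (assumed protonated at
physiological pH). Receptor residues carry no bond table in PDB, so their
connectivity is perceived from covalent radii (+0.40 Å tolerance); only
connectivity is used, never bond orders.

Occupancy is 100 × (poses with bit) / |subset|, reported to one decimal.
π–π and cation-π contacts are *not* fingerprint bits: they feed only the
pharmacophore stage, so the fingerprint counts hydrogen-bond and hydrophobic
interactions only.

## Halogen-bond triage

A C-bound halogen's σ-hole lies on the extension of the C–X axis; its
donor strength orders I > Br > Cl, and F is never a donor. Contacts are
collected within a 4.5 Å census cutoff (wider than any pass criterion, so
near-misses stay visible) and classified with strict inequalities:

| criterion | Cl | Br | I |
|---|---|---|---|
| d(X···O/N/S) | < 3.27 Å | < 3.37 Å | < 3.50 Å |
| ∠C–X···partner | > 150° | > 150° | > 150° |
| acceptor-side angle | > 90° | > 90° | > 90° |

and, for the perpendicular X-as-acceptor mode against a polar hydrogen:
d(X···H) > 2.8 Å, ∠C–X···H > 90°, ∠(donor)–H···X > 120°. The distance
bound for X···H is implemented exactly as stated, as a *lower* bound, even
though an upper bound would be the usual convention for a contact criterion;
the direction is exposed as a configuration flag (`xh_bound_is_lower`)
rather than silently corrected, so data prepared under either convention
can be classified faithfully. The acceptor-side angle generalises the
carbonyl case (∠C=O···X) to any partner by using the partner's heaviest
attached atom; the generalisation is noted in the classification trace.
Every threshold comparison is recorded in that trace, so a classification
can always be audited.

Ring positions are graph distances around the scaffold's aromatic ring from
the attachment carbon (1 → ortho, 2 → meta, 3 → para); halogens on
non-scaffold rings are "other", on sp³ carbons "aliphatic". Frequency
analysis reports, per (position, element), the fraction of poses of ligands
*bearing that decoration* that have ≥ 1 passing contact — the denominator
choice matters and is deliberate: a para-chloro ligand's poses should not
dilute the meta-iodo statistics.

QM candidate selection takes, per ligand, the minimum-ΔG pose among
consensus-cluster poses with ≥ 1 passing contact (pose-id tie-break);
ligands with no passing pose are reported unselected rather than forced.

## Surface electrostatics

The potential is evaluated in atomic units (bohr, hartree) and reported in
kcal/mol (× 627.509, two decimals).

* **Point sources**: direct Coulomb sums; evaluation within 10⁻⁶ bohr of a
  source is an error rather than a silent infinity.
* **Density grids** (Gaussian cube files): trapezoidal node quadrature of
  ∫ρ/|r′−r|; nodes within half a cell of the evaluation point contribute
  instead through the closed-form Newtonian potential of a uniformly charged
  box (corner-sum formula with principal-value arctangents, valid inside and
  outside the cell). The refinement study in the tests shows the quadrature
  converging on the point-charge limit for a narrow Gaussian.
* **Isosurface**: marching cubes at ρ = 0.001 au with linear edge
  interpolation; a contour touching the grid boundary is an error
  ("grid too small"), an isovalue above the grid maximum a warning plus an
  empty surface. For a spherical Gaussian density the surface radius matches
  the analytic solve within one grid spacing and the area converges to
  4πr².
* **Extrema**: local maxima/minima over the 1-ring vertex adjacency of the
  mesh; assignment to atoms is nearest-atom (simple, deterministic — a
  bond-Voronoi scheme would change little on convex surface patches but cost
  auditability). Both the global V_S,max/V_S,min and, per halogen, the most
  positive halogen-assigned local maximum (the σ-hole potential) are
  reported; a constant surface is flagged flat. A degenerate plateau of
  exactly equal neighbouring values would report each plateau vertex as an
  extremum; with floating-point field values this does not occur in
  practice.

**Empirical ligand model.** The package never runs SCF; quantum densities
and potentials are consumed as externally produced cube files. For
halogenated ligands without a quantum backend it builds a documented
empirical model:

* charges: MMFF94 atomic partial charges;
* σ-hole anisotropy: a fixed point dipole on each C–X axis at the halogen
  (Cl 0.50 D, Br 0.75 D, I 1.00 D, realised as ± charges 0.30 bohr apart),
  magnitudes chosen once to follow the halogen polarizability order;
* surface: a promolecule density — superposed single-ζ valence Slater
  atomic densities (outermost-shell exponents; e.g. Cl 3p ζ = 2.039 bohr⁻¹
  gives a 0.001 au atomic radius of 1.91 Å) plus a tight Gaussian core term
  (0.05 e bohr⁻³, width 1.1 bohr) for elements with core electrons. The
  core term exists because a valence-only radial density vanishes at the
  nucleus as r^(2n−2), which would open spurious interior cavities under
  the outer isosurface for Br and I; at the 0.001 au surface itself it is
  below 10⁻⁷ au and does not move the surface.

This model reproduces the *qualitative* σ-hole physics — a positive cap on
the C–X extension, strength ordering I > Br > Cl, sensitivity to
electron-withdrawing substitution — but its absolute V_S,max values are
force-field-grade, not DFT-grade: point charges plus a single fixed dipole
cannot reproduce the magnitude of the quantum charge-density anisotropy,
and the values it prints (the acceptance script reports them for the
para-bromo and para-chloro analogues) sit tens of kcal/mol in scale below
typical B3LYP-level surface potentials for the same compounds. Treat them
as ordering/screening quantities; supply real cube files for quantitative
σ-hole magnitudes. Conformer choice also matters at the several-kcal/mol
level for amino acids (intramolecular H-bonding shifts ring polarisation),
which is why the acceptance script embeds and relaxes a seeded conformer
rather than asserting a canonical geometry.

## Energetics

ΔG_bind = G_complex − G_protein − G_ligand is validated to 10⁻⁹ kcal/mol on
ingest when both the components and the difference are present; ΔΔG is
(refined − docking). Spearman uses average ranks on ties; both r_s and r²
return NaN with a logged warning on constant input (an error would abort
batch tables over legitimately degenerate subsets). Implementations are the
standard library routines; the test suite pins them against brute-force
rank-then-Pearson and covariance-formula oracles to 10⁻¹².

## Pharmacophore derivation

One feature per detected interaction: HBD/HBA unit vectors from the ligand
atom toward the residue partner; one hydrophobic sphere (radius 1.5 Å) per
contiguous cluster of contacting apolar atoms, where contiguous means bonded
or within 2.0 Å — note the clustering runs over *contacting* atoms only, so
a halogen whose ipso carbon makes no contact forms its own feature even
though it is bonded to the ring; an XBD vector along C–X for every passing
halogen bond; and a positive-ionizable feature for a cationic atom engaged
in a cation-π contact (ring centroid ≤ 6.0 Å). PI is keyed to cation-π
rather than to any contact of the cationic atom: the ammonium also donates
hydrogen bonds, and tying PI to those would make PI redundant with HBD and
unable to distinguish an interaction-poor mode. π–π (edge-to-face) is
annotated at centroid–centroid ≤ 5.5 Å with interplanar angle ≥ 60°; these
aromatic-interaction cutoffs are conventional values and configurable.
Excluded volumes are one 1.5 Å sphere per receptor heavy atom within 5.0 Å
of the ligand.

## Synthetic data generator

The generator emulates the *shape* of a transporter docking study, not its
energetics: 8 halogen-decorated amino-acid ligands on a phenylalanine core
(meta/para iodo-tyrosines, ortho/para bromo α-methyl analogues, a
meta-fluoro tyrosine, para-chloro, and two chloroethyl/aliphatic-chlorine
analogues), a pocket of ~9 residue fragments — two backbone N–H donors
aimed at the carboxylate oxygens, three backbone carbonyls accepting the
ammonium hydrogens, one backbone carbonyl on the meta C–I axis as the
halogen-bond acceptor, an aromatic ring within cation-π range, and apolar
fragments against the benzylic edge and the meta-substituent tips — and
100 poses per ligand: 80 mode-anchored (two modes of 40) plus 20 uniform
random decoys.

Key mechanics:

* Every ligand's scaffold torsions (carboxylate, χ1/χ2, ammonium rotor) are
  snapped to a single reference conformer before rigid alignment, so all
  ligands present the amino-acid moiety identically and the planted
  hydrogen-bond geometry carries over; the α-methyl analogues have their
  quaternary stereocentre fixed to the L-like configuration for the same
  reason. A ligand with a single meta halogen has its ring flipped (a pure
  relabelling of an equivalent geometry) to put the halogen on the
  acceptor side.
* Mode 2 keeps the amino-acid moiety fixed and swings the side chain: the
  χ1/χ2 rotation is chosen by scanning candidates for the placement with
  maximal automorphism-minimised scaffold RMSD from mode 1, required to
  exceed twice the clustering height.
* Rigid jitter (translation uniform in a ball of radius 2σ, rotation up to
  8σ degrees, σ = 0.5 Å by default) is accepted only if (i) the pose's
  scaffold RMSD to its mode reference stays below
  min(h/2, (separation − h)/2) − 0.05 — by the triangle inequality this
  *guarantees* every intra-mode pair sits below the clustering height h and
  every cross-mode pair above it, so consensus recovery is a theorem of the
  construction, not a statistical accident — and (ii) the production
  detectors, run at thresholds tightened by 0.2 Å / 5°, find exactly the
  planted interaction set, and at thresholds loosened by the same margins
  find nothing more. Failing draws are redrawn. The generator thus verifies
  its plants through the same code paths the analysis uses instead of
  trusting construction arithmetic; the accepted-jitter distribution is
  therefore mildly truncated relative to the nominal ball, which is
  irrelevant to what the plants certify.
* Decoys must stay further than h + cap + 0.25 in scaffold RMSD from both
  mode references (so they cannot join a mode cluster under complete
  linkage) and must carry no margin-loosened passing halogen contact
  (their ground truth plants nothing, and a chance σ-hole hit would
  mislabel them); incidental decoy hydrogen bonds are allowed — real decoys
  have them too.
* All randomness flows from one seeded generator; equal seeds give
  byte-identical SDF/PDB output.

**What passing tests show — and don't.** Mode recovery and detector
completeness on this generator certify the *machinery*: the clustering cut,
the CSC rule, the geometric detectors and the bookkeeping are exact on data
whose ground truth is known by construction. They do not certify behaviour
on real docking output, where modes are not isotropic Gaussian clouds,
inter-mode separations are not guaranteed, protonation states are
heterogeneous, and the receptor is not rigid fragments. Mock energies are
correlated noise with a component-consistency identity, not physics; the
correlation statistics they feed are exercised for correctness, not
calibrated against experiment.

## Sizes and determinism

Default problem sizes (8 ligands × 100 poses, ~60-atom pocket, 0.25–0.45
bohr ESP grids) were chosen so the full test suite and the acceptance
script each complete in well under a minute of compute on one core while
keeping the 800 × 800 joint clustering of the study design intact. The
pipeline is a pure function of (inputs, configuration, seed): outputs are
serialised with sorted keys and no timestamps, and rerunning a configuration
reproduces `report.json` byte for byte.

## Known limitations

* The empirical σ-hole model is ordering-grade, as discussed above.
* Heavy-atom-only hydrogen-bond detection cannot resolve donor directionality
  better than the ∠R–D···A ≥ 90° cone; explicit hydrogens are preferred.
* The scaffold is supplied, not discovered: no maximum-common-substructure
  search.
* X···π halogen contacts are recorded in the census but never classified as
  bonds (no printed criteria; they fall under "unsupported acceptor").
* Cube files must be axis-aligned with positive (bohr) axis counts.
* No protonation-state prediction: poses are analysed as given.
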