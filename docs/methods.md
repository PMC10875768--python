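# Methods

## Coordinate model

Files are parsed with gemmi (PDB and mmCIF; first model only) into a thin
chain → residue → atom hierarchy addressed by author numbering
`(chain_id, seq_num, icode)`. Alternate conformers are resolved at parse
time to a single conformer — highest occupancy wins, ties break toward
altloc `A` — so all downstream geometry is single-valued and
deterministic. Hydrogens are retained when present, but every default
criterion (SASA, contacts) operates on heavy atoms only, because the
target use case is X-ray structures near 2.4 Å resolution, which carry no
hydrogen positions. Waters are kept and flagged (`HOH`/`WAT`); they are
excluded from SASA and from direct protein–protein contact groups, and
consulted only by the water-bridge detector.

Residue numbering is always the file's author numbering. Antigen positions
in the mucin TM-relative frame (labels counting down toward the membrane)
are handled as an explicit label map supplied by the caller, never by
renumbering atoms; the deposited numbering scheme of a given entry must be
established by inspecting the file, so chain identities and ranges are
config data rather than constants.

## SASA and interface area

Shrake–Rupley with a deterministic spherical Fibonacci point set; no RNG
anywhere in the area computation, so results are bit-reproducible.
Defaults: probe 1.4 Å, 960 points per atom (doubling the count moves a
two-sphere test area by well under 1%). Radii are a Chothia-style protein
set — tetrahedral C 1.87 Å, trigonal (carbonyl, carboxyl, amide, aromatic,
guanidinium) C 1.76 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å — overridable per
element or per `RES:ATOM` from a YAML table, since published interface
areas depend on the (often unstated) radii of the tool that produced them.

Buried area between groups A and B is computed from three SASA evaluations
(A, B, A∪B). Per-residue burial is the drop in the residue's SASA on
complex formation, so burials sum to the total exactly up to float
rounding. Both the total buried area and its half (the convention PISA
prints as "interface area") are reported; comparisons against
PISA-derived literature values should use the half.

## Contact criteria

Hydrogen bonds use heavy-atom donor/acceptor chemistry per residue type
(backbone N except proline; Ser/Thr/Tyr hydroxyls; Asn/Gln amides;
Arg/Lys/His/Trp nitrogens; backbone O/OXT; Asp/Glu/Asn/Gln oxygens; His
ring nitrogens), distance ≤ 3.5 Å, and — when the donor's covalent
antecedent exists in the model — an antecedent–donor–acceptor angle ≥ 90°.
The permissive angle floor is deliberate: without hydrogens a tighter
angular test would reject genuine bonds at the resolution this targets.
A residue pair may contribute several bonds; counting is per atom pair.
His is treated as positively charged by default (`his_positive=True`),
appropriate for structures crystallised at acidic pH, and configurable.
Water bridges apply the hydrogen-bond distance on both legs and report the
longer leg as the contact distance. Contact inventories carry a parameter
fingerprint; differencing two inventories produced under different
parameters is an error. Diffs match contacts by kind plus unordered
(residue, atom-name) pairs and ignore distance, so a lengthened bond
counts as lost only once it leaves the inventory.

Neighbour search uses a KD-tree; a brute-force O(n²) scan is kept as a
test-time cross-check and the two are asserted to agree exactly.

## Superposition and displacement

Kabsch superposition via SVD with the determinant correction, so a proper
rotation is always returned even for near-planar atom sets. "Backbone
atoms" for RMSD means N, CA, C, O of residues ordered in both structures;
residues missing any of the four are excluded. For apo-vs-bound
comparison the global fit uses framework (non-CDR, non-linker) backbone
atoms so loop movements are measured rather than absorbed, while each
domain's reported RMSD comes from that domain's own least-squares fit,
mirroring domain-by-domain superposition practice. Side-chain movements
are measured per atom; aromatic-ring movement is the distance between
six-membered-ring heavy-atom centroids (Tyr/Phe: CG, CD1, CD2, CE1, CE2,
CZ), because "the ring moved" does not name an atom. Dihedrals follow the
IUPAC sign convention, reported in degrees on (−180, 180] with ties at the
branch cut reported as +180.

## Motifs

β-turn gate: CA(i)–CA(i+3) ≤ 7.0 Å over four consecutively numbered
residues; a window is rejected only if *both* central residues are helical
((φ,ψ) within ±30° of (−60,−45)), the standard way of excluding contiguous
helix. Typing uses the Hutchinson–Thornton windows (±30°, one angle ±45°)
around the canonical centres; a turn fitting no centre is reported as
type IV/unclassified, and the mirror of type I is reported as I′. The
i→i+3 stabilising hydrogen bond is annotated when present but not
required. Hairpins are seeded by reciprocal N(i)···O(j) / O(i)···N(j)
backbone bonds with j ≥ i+2; register pairs sharing the same chain-reversal
centre (equal i+j) are merged into one hairpin, and ≥ 2 cross-strand bonds
are required.

The sequon scan is the N-X-[S/T] (X ≠ P) rule with overlapping matches.
No O-glycosylation model is implemented: O-site calls in the literature
are tool-derived predictions, so they can only be imported as external
annotations, not recomputed from a rule. Percent identity of aligned
sequences uses pairwise deletion of gapped columns — an explicit choice,
since published "% identity" figures rarely state their gap handling.

## scFv annotation and comparison

Domain architecture (V_H, linker, V_L) and CDR loops are configuration
data: explicit residue ranges in sequential construct numbering, with the
4H11 ranges (V_H 1–123, linker 124–148, V_L 149–261; CDRs H1 26–32,
H2 53–56, H3 100–110, L1 174–186, L2 204–206, L3 245–248) as defaults. A
Kabat/Chothia/IMGT numbering engine is a large subsystem out of scope here,
and explicit ranges make the mapping auditable. Annotation resolves the
ranges against the coordinates and flags in-range residues absent from the
model as disordered (e.g. a flexible Gly-Ser linker without electron
density). The paratope–epitope map groups every detected scFv–antigen
contact under the CDR owning its antibody-side residue (or the domain
framework) and characterises the antigen interface separately against V_H
and V_L as two interface reports.

## Synthetic data

The generator produces fixtures whose expected values come from
construction arithmetic, never from the code under test: single spheres
(closed-form area), sphere pairs (spherical-cap closed form), ideal
donor–acceptor pairs at requested distance/angle, a cation over a ring
centroid, a bridging water with equidistant legs, backbones grown by
natural-extension-of-reference-frame placement from ideal bond geometry
(N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å) that reproduce requested
(φ,ψ,ω) to ≪ 0.5°, a manually placed antiparallel hairpin, two flat walls
at a controlled gap, and rigid copies under a known rotation/translation
with optional seeded isotropic Gaussian noise (E[RMSD²] = 3σ² for large
n). Fixtures are emitted as standard PDB files with JSON ground-truth
sidecars so the full I/O path is exercised; a fixed seed makes output
byte-identical.

What the fixtures do **not** emulate: realistic packing density, rotamer
statistics, crystallographic waters beyond the placed bridges, alternate
conformers under strain, or experimental coordinate error. Passing the
synthetic suite therefore demonstrates the correctness of the geometry and
accounting, not the biological tuning of the default cutoffs; the cutoffs
themselves follow common practice in the interface-analysis literature and
are all configurable.

## Independent oracles used in tests

Single- and two-sphere closed forms; a latitude–longitude surface
quadrature (a different integration scheme from the Fibonacci point
count); biotite's Shrake–Rupley as a third-party SASA cross-check;
scipy's `Rotation.align_vectors` against the in-package Kabsch; a second
dihedral formula (projection onto the central bond); a plain-loop
nearest-centre turn classifier evaluated exhaustively on a 10° grid; and
brute-force pair scans against the KD-tree path.

## Reproduction against deposited structures

The published measurements this package is designed to reproduce (V_H–V_L
interface of ~926 Å² in the PISA convention, V_H/V_L–antigen split of
~617/301 Å², 11 interface hydrogen bonds, an R44–F251 cation-π pair at
~5.6 Å, apo-vs-bound domain RMSDs of 0.454/0.355 Å, S180 OG and Y108 ring
movements of ~2.5/~3.8 Å, a 19-residue ordered antigen peptide forming two
consecutive β-turns typed I and I′ plus a hairpin bonded at 2.8/3.1 Å)
require the deposited coordinate files, PDB entries 8VRS (free scFv) and
8VRR (complex). The test layer locates the scFv chain by its construct
numbering, finds the antigen peptide, and derives the TM-relative label
offset by matching the modelled sequence into the printed 26-mer rather
than assuming a numbering scheme. These tests fail with an explicit
message when the files are not present locally; they do not download.

Two published figures are internally inconsistent in their source and are
deliberately not reconciled here: the Y108 movement is quoted both as
~3.8 Å and as 3.3 Å, and the new bound-state hydrogen-bond partner of
S197 is quoted both as Q115 and Q196. The comparison report simply states
what the coordinates support.

## Known limitations

No solvent-excluded (Connolly) surface, no interface energetics or
complexation significance, no DSSP-style secondary-structure assignment,
no flexible or sequence-driven superposition, no paratope prediction, no
assembly/symmetry expansion. Hydrogen-bond detection without hydrogens is
intrinsically permissive; counts should be compared across states computed
under one parameter set (the inventory fingerprint enforces this) rather
than against counts from tools with different criteria.
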