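# Methods

This note documents the models, conventions and numerical choices behind
`propellervar`, and what the synthetic generator does and does not emulate.

## Structure model

One chain of a PDB/mmCIF file is read (gemmi), HETATM compounds other than
modified amino acids are dropped, waters and models beyond the first are
ignored, and alternate locations resolve to the highest-occupancy conformer
(ties keep file order). Author numbering is used throughout;
`missing_numbers` records numbering gaps inside the retained span, so that
resolved plus missing numbers tile the domain range whenever insertion codes
are absent. Non-standard residues with a clear parent (MSE, SEP, …) map to
the parent with a warning; anything else is dropped with a warning. Variant
tables are assumed to share the structure's numbering; a `numbering_offset`
config parameter (default 0) reconciles them when they do not.

## Propeller axis and axial (Z) projection

A β-propeller is disc-like, so its symmetry axis is taken as the direction
of minimal variance of the CA coordinate cloud (smallest eigenvector of the
CA covariance; `principal` mode). A `crystal_z` mode uses the deposited +Z
instead, for structures deposited with the propeller axis along Z. A
degenerate eigengap (relative gap < 1e-6) raises an error advising
`crystal_z`. The axis sign is fixed by an anchor rule: the mean projection
of the anchor residues — by default the tetrad aspartates, which sit at the
top of each blade — must exceed the domain mean, making the top face
positive; an explicit flip flag overrides.

Each residue's backbone **carbonyl carbon** is projected
(z = (r − centroid)·axis); CA substitutes only with a warning. The origin is
the CA centroid, so only relative z is meaningful — all group statistics
are rank-based, making the origin immaterial. Unresolved residues inside
the domain get linearly interpolated z between their nearest observed
neighbours (in residue number); gaps touching the domain boundary are left
absent with a warning. Interpolation is exact at gap endpoints and monotone
within each gap.

## Blade segmentation and motif alignment

β-strands are detected from main-chain hydrogen-bond ladders (runs of ≥ 3
consecutive residues participating in inter-strand rungs); ladder-connected
strands form one blade, reported as an inclusive residue range in sequence
order. Automatic segmentation is best-effort: user-supplied ranges are the
authoritative path and are validated and passed through verbatim.

Blades are superposed pairwise by closed-form least squares (SVD Kabsch,
proper rotation enforced) on CA correspondences obtained by sequence-order
dynamic programming over spatially compatible pairs (≤ 4.5 Å after
superposition), iterated with re-superposition. The reference blade is the
one participating in the most correspondence pairs (ties: lowest index).
Motif numbering is calibrated on sequence conservation in space: the
reference column whose members are most often aspartate becomes position
26, which forces the tetrad His/Ser-Thr/Trp columns onto 4/22/32; each
blade's positions 1–32 then follow by sequence offset from its aspartate.
Absence of an aspartate-consensus column raises a calibration error (the
domain is probably not a WD40 propeller). Residues outside every 1–32
window are unaligned.

## Hydrogen bonds and DHSW tetrads

Crystal structures at typical resolution lack hydrogens, so bonds are
called on heavy atoms: donor–acceptor (N/O) distance ≤ 3.5 Å (configurable)
and antecedent–donor–acceptor angle ≥ 90°. Same-residue pairs are excluded,
as are main-chain–main-chain pairs of sequence-adjacent residues (covalent
neighbourhood). His ND1/NE2 act as donor or acceptor in either direction —
tautomer and protonation states are not modelled. Detection is validated
against an exhaustive all-pairs scan under identical criteria.

A tetrad record per blade holds the residues found at motif positions
26/4/22/32. **Completeness is a sequence-identity property** (Asp; His; Ser
or Thr; Trp), never an energetic one: the hydrogen-bond network among
members is reported alongside but cannot demote completeness.
`asp_backbone_bonds` lists bonds from the Asp carboxylate oxygens to any
main-chain nitrogen — the interactions that pin the hairpin at the top of
each blade.

## Burial and conservation

Relative solvent accessibility uses Shrake–Rupley sphere sampling: each
atom's solvent-expanded sphere (vdW + 1.4 Å probe) is covered with 960
quasi-uniform points (golden-spiral lattice; deterministic), and the
exposed fraction times the sphere area gives the atom's SASA. Residue SASA
is normalized by extended Gly-X-Gly reference values (theoretical maxima,
Tien et al. 2013) and clipped to [0, 1] with a warning. The sampler is
validated against a 10⁴-point refinement of itself on a peptide fixture
(≤ 2 % per atom).

Conservation is 1 − H/ln 20 per alignment column, with gaps excluded from
the distribution, Miller–Madow small-sample bias correction applied to the
plug-in entropy, and columns over 50 % gaps flagged. Columns map to domain
numbering through the ungapped reference row, whose length must equal the
domain's residue count. Any monotone-equivalent conservation score would
give identical rank-based group statistics.

## Group statistics

Five residue groups are compared pairwise per feature: diagnostic,
tetrad (all members of all tetrad records), hotspot (a user-supplied
top-face list; absent list disables the group rather than guessing),
population, and all domain residues; a residue may belong to several
groups. Variant groups are deduplicated to unique residues by default
(matching the 6-residue vs 29-residue design); an all-variants mode exists.
The default test is the two-sided Mann–Whitney U — robust, origin-free, and
consistent with boxplot presentation — with the exact null enumerated when
n_a·n_b ≤ 2000 and the pooled sample is tie-free, else the tie- and
continuity-corrected normal approximation. Welch's t is available for
sensitivity analysis. Raw p-values are reported; Holm adjustment is
available but off by default. Published p-values for this comparison do not name the
test behind them, so agreement with them is by design assessed at order of
magnitude only.

## The synthetic generator

The generator emulates, with known ground truth: (a) an idealized N-bladed
propeller written as a PDB file; (b) variant tables with a planted axial
shift between diagnostic and population groups; (c) an MSA with planted
per-column conservation; (d) external pathogenicity-score tables correlated
with the planted pathogenicity signal.

**Blade geometry.** Each blade is a four-strand ladder in a local slab frame
(strand spacing 4.8 Å) with the per-residue axial rise set to 2 Å — real
propeller strands are inclined to the axis, so their axial rise is well
below the 3.3 Å backbone rise. Strand residues carry full N/CA/C/O
backbones whose N/O offsets realize the inter-strand rungs
(O···N ≈ 2.9 Å); connector (loop/turn) residues carry a sparse CA +
carbonyl-C backbone, since only the carbonyl carbon feeds downstream
analysis and a physically meandering loop is outside the generator's scope
(motif position 5 additionally carries its main-chain N, a planted Asp bond
target). The tetrad positions 4/22/26/32 sit at the blade top; pseudo
sidechain atoms for Asp/His/Ser/Trp members are placed algorithmically:
each functional atom is put 2.85 Å from its intended partner, within
sidechain reach of its CA, at least 3.9 Å from every other polar atom (so
no unplanned bond can form even under coordinate noise), with donor-angle
validity enforced. The planted network per complete tetrad: His NE2–Asp
OD1, Ser OG–His ND1, Trp NE1–Asp OD2, plus Asp OD1 → main-chain N of
position 5 and Asp OD2 → main-chain N of position 28 (two below the Asp).
Blades are arranged with n-fold symmetry about the planted axis at ring
radius 26 Å; Gaussian coordinate noise is applied last; a single seeded
stream drives all randomness.

**What it does not emulate.** No velcro closure (each blade is a
self-contained ladder, whereas real propellers close the ring by sharing a
strand); loops may contain non-physical CA–CA gaps; only tetrad members
carry sidechain atoms, so absolute SASA values are those of a sparse-atom
model; sidechain rotamers and backbone dihedrals are not physical. Passing
tests on this geometry therefore demonstrate the correctness of the
algorithms against planted ground truth, not robustness to the full
irregularity of experimental structures — for real structures, the
user-supplied blade-range path and the crystal_z axis mode are the
conservative options.

**The TBLR1-like preset** (`tblr1_like_spec`) is a synthetic stand-in for
the TBLR1 WD40 domain: domain span 153–514, blade starts
162/210/262/303/345/390/438/480 derived arithmetically from the published
motif anchors (His213 = 4, Leu282 = 21, Asp328 = 26, His348 = 4 with
Asp370 = 26/Ser366 = 22/Trp376 = 32, His441 = 4, Pro444 = 7; the three
unanchored blades are spaced evenly), real residue identities planted at
all variant and anchor positions, six complete tetrads, one tetrad missing
only the Trp (blade 6), and one blade carrying only the conserved Asp
(blade 8), so the position-26 aspartate is present in all eight blades.
Which blade lacks which member is not derivable from the collated tables,
so the assignment of the degraded tetrads to blades 6 and 8 is a generator
convention. The hotspot preset is the solvent-exposed top-face template
positions {5, 7, 23, 25} across blades. The planted conservation profile
puts 0.95 at tetrad positions, 0.7 at top-face shoulders, 0.5 on strands
and 0.25 on loops.

**Variant generation** samples diagnostic residues from the smallest
top-face subset whose mean planted z exceeds the domain mean by the
requested shift (threshold found by bisection), population residues
uniformly, and re-draws a configurable fraction of population variants at
already-used residues to emulate recurrent positions. Default group sizes
are 6 diagnostic vs 29 population with a 6 Å shift, the study design of
the motivating comparison. **MSA generation** realizes each column as an
exact consensus-vs-uniform composition whose normalized entropy matches
1 − planted score (consensus probability solved by bisection, rows
shuffled), so the planted value is carried by the sample itself.

## Numerical choices

- H-bond cutoff 3.5 Å, angle 90°, both configurable; deterministic output
  ordering by (donor, acceptor).
- Superposition correspondence cutoff 4.5 Å, 3 refinement iterations;
  blades with < 4 CAs are skipped with a warning.
- SASA: 960 points, probe 1.4 Å; radii C 1.70/N 1.55/O 1.52/S 1.80 Å.
  The pipeline's default point count is reduced (240) for turnaround; the
  library default stays 960.
- Exact-vs-normal switch for the U test at n_a·n_b = 2000 and tie-free.
- Null-calibration and power checks use 1500 replicates (the exact test's
  discrete size at n = 6 vs 29 is ≈ 0.05, and the replicate count keeps the
  Monte-Carlo error of the estimated rate near ±0.006).
- Problem sizes throughout the test-suite and the acceptance script (one
  362-residue propeller, 150–500-sequence alignments, ≤ 1500 replicates)
  were chosen so a full run completes in well under a minute on one CPU.

## Known limitations

- Automatic blade segmentation assumes regular ladders; highly distorted or
  low-resolution sheets should use explicit ranges.
- Motif assignment is offset-based within each blade after spatial
  calibration, so blades with internal insertions/deletions relative to the
  reference can drift near loop boundaries (assignments at the tetrad
  anchors are calibrated directly and are stable).
- The interpolated z of long unresolved stretches is only as good as
  linearity in residue number; such values are flagged `interpolated` and
  carried into the statistics like observed ones.
- External scores (PolyPhen/SIFT) are consumed, never computed; genomic
  coordinates are opaque metadata (no transcript mapping).
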