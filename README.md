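# propellervar

Structural triage of missense variants in WD40 β-propeller domains.

## The problem

The WD40 domain is one of the most abundant folds in eukaryotic proteomes: a
toroidal β-propeller of (typically eight) four-stranded antiparallel sheets
("blades") arranged around a central axis, whose *top face* mediates
protein–protein interactions. Clinical sequencing keeps producing novel
missense variants in WD40-containing disease genes (the motivating case is
*TBL1XR1*, whose WD40 domain binds β-catenin) with no per-variant functional
evidence. Two structural signals discriminate likely pathogenic from benign
variation in this fold:

1. **The DHSW tetrad.** Each blade is thermostabilized by an
   Asp–His–Ser/Thr–Trp sidechain hydrogen-bond network at canonical motif
   positions 26/4/22/32 of the 32-column WD40 repeat. The aspartate at
   position 26 additionally pins the β-hairpin at the top of its blade
   through two hydrogen bonds to main-chain nitrogens. Variants at tetrad
   positions compromise fold stability.
2. **Axial position.** Projecting each residue's backbone carbonyl carbon
   onto the propeller's central axis gives a signed coordinate *z* between
   the top (binding) and bottom faces. Likely pathogenic variants cluster
   toward the top face; presumed-benign population variants do not.

`propellervar` implements the full analysis: structure parsing, blade
segmentation from main-chain hydrogen-bond ladders, structure-based motif
alignment calibrated on the conserved aspartate column, DHSW tetrad
detection, axial projection with linear interpolation for unresolved
residues, relative solvent accessibility (Shrake–Rupley), alignment-column
conservation (1 − normalized Shannon entropy, Miller–Madow corrected), and
rank-based group statistics over the residue classes
{diagnostic, tetrad, hotspot, population, all residues}:

> for groups *A*, *B* with feature values, a two-sided Mann–Whitney *U* test
> (exact null when *n<sub>A</sub>·n<sub>B</sub>* ≤ 2000 and tie-free, else the
> tie- and continuity-corrected normal approximation), with Welch's *t*
> available for sensitivity analysis.

A synthetic-propeller generator with known ground truth (axis, blade ranges,
motif positions, tetrad statuses, per-residue *z*) makes every stage testable
without downloading any structure, and ships a **TBLR1-like preset**: a
synthetic stand-in on the real TBL1XR1 residue numbering (domain 153–514)
with the published motif anchors planted (His213/His441 at position 4,
Leu282 at 21, Asp328/Asp370 at 26, Pro444 at 7, the blade-5 tetrad
Asp370/His348/Ser366/Trp376, six complete tetrads and one missing only the
tryptophan). A real crystal structure (e.g. PDB 4lg9) can be passed through
the identical pipeline.

## Worked example

```python
from importlib import resources
from propellervar import (segment_blades, superpose_blades, assign_motif_positions,
                          detect_hbonds, identify_tetrads, compute_axis,
                          project_residues, interpolate_missing, annotate,
                          parse_variant_table, filter_domain_variants, run_group_suite)
from propellervar.synth import tblr1_like_spec, generate_propeller

# synthetic stand-in for the TBLR1 WD40 domain (8 blades, real numbering)
domain, truth = generate_propeller(tblr1_like_spec(noise=0.05, seed=1))

blades = segment_blades(domain)
motif = assign_motif_positions(blades, superpose_blades(domain, blades), domain)
tetrads = identify_tetrads(motif, domain, detect_hbonds(domain))
print(f"blades: {blades.n_blades}, complete tetrads: {sum(t.complete for t in tetrads)}")
print(f"Leu282 motif position: {motif.position_of(282)}, Pro444: {motif.position_of(444)}")

asp = {t.members['D'] for t in tetrads if t.members['D'] is not None}
frame = compute_axis(domain, anchor_residues=asp)   # top face positive
proj = interpolate_missing(project_residues(domain, frame, "C"), domain)

table = resources.files("propellervar") / "data/table2_variants.tsv"
variants = filter_domain_variants(parse_variant_table(str(table)), domain.domain_range)
ann = annotate(variants, projection=proj, motif=motif, tetrads=tetrads, domain=domain)
z = {n: e.z for n, e in proj.entries.items()}
for r in run_group_suite(ann, {"z": z}, tetrads=tetrads,
                         all_residue_numbers=[x.author_number for x in domain.residues]):
    if (r.group_a, r.group_b) == ("diagnostic", "population"):
        print(f"diagnostic (n={r.n_a}) vs population (n={r.n_b}): "
              f"U = {r.statistic:.0f}, p = {r.p_value:.1e}, "
              f"median z {r.summary_a[2]:+.1f} vs {r.summary_b[2]:+.1f} A")
```

prints

```
blades: 8, complete tetrads: 6
Leu282 motif position: 21, Pro444: 7
diagnostic (n=6) vs population (n=29): U = 165, p = 1.1e-04, median z +4.5 vs -1.8 A
```

The six residues carrying likely pathogenic de novo missense mutations sit a
median 6.3 Å nearer the top face than the 29 residues carrying presumed
benign population variation; with U = 165 of a possible 174, the exact
rank test puts this at p ≈ 10⁻⁴.

The variant table dialect (`data/table2_variants.tsv` is the packaged
collation of all missense variants overlapping the domain) is a TSV with
columns `Variation` (Diagnostic/Population), `Source (allele count)`,
`Location (GRCh37)`, `Ref/alt`, and `Predicted amino acid change` in
three-letter HGVS p. notation, e.g. `p.(His441Arg)`.

## Command line

```sh
propellervar synth --out bundle/ --seed 1          # structure.pdb, variants.tsv, msa.fasta, truth.json
propellervar run --structure bundle/structure.pdb \
    --variants bundle/variants.tsv --msa bundle/msa.fasta --out report/
propellervar project --structure mydomain.pdb      # per-residue z TSV
propellervar tetrads --structure mydomain.pdb      # per-blade DHSW status
```

`run` writes `projection.tsv`, `alignment.txt` (the blades-by-motif-position
text alignment), `tetrads.tsv`, `annotated_variants.tsv`,
`comparisons.json` and `report.json` into the output directory,
deterministically for a fixed config and seed.

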