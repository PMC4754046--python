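"""Shared fixtures: synthetic propellers, the packaged variant tables, and a
tiny hand-written PDB file."""

import numpy as np
import pytest
from importlib import resources

from propellervar import (segment_blades, superpose_blades, assign_motif_positions,
                          detect_hbonds, identify_tetrads, compute_axis,
                          project_residues, interpolate_missing)
from propellervar.synth import (SyntheticPropellerSpec, generate_propeller,
                                tblr1_like_spec)

# a 3-residue Gly-Ala-Gly peptide, 12 atoms, author numbers 1-3
THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1      -0.900  -0.500   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       0.900   0.600   0.200  1.00  0.00           C
ATOM      4  O   GLY A   1       1.100   1.800   0.400  1.00  0.00           O
ATOM      5  N   ALA A   2       3.000  -0.900   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.900  -0.400   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       4.800   0.200   0.200  1.00  0.00           C
ATOM      8  O   ALA A   2       5.000   1.400   0.400  1.00  0.00           O
ATOM      9  CB  ALA A   2       3.900  -1.600   1.200  1.00  0.00           C
ATOM     10  N   GLY A   3       6.900  -1.300   0.000  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.800  -0.800   0.000  1.00  0.00           C
ATOM     12  C   GLY A   3       8.700  -0.200   0.200  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def three_residue_pdb(tmp_path_factory):
    p = tmp_path_factory.mktemp("fix") / "gag.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture(scope="session")
def three_residue_gap_pdb(tmp_path_factory):
    lines = [l for l in THREE_RESIDUE_PDB.splitlines(keepends=True)
             if " A   2 " not in l]
    p = tmp_path_factory.mktemp("fix") / "gag_gap.pdb"
    p.write_text("".join(lines))
    return p


@pytest.fixture(scope="session")
def table1_path():
    return str(resources.files("propellervar").joinpath("data/table1_variants.tsv"))


@pytest.fixture(scope="session")
def table2_path():
    return str(resources.files("propellervar").joinpath("data/table2_variants.tsv"))


@pytest.fixture(scope="session")
def generic_propeller():
    """Symmetric 8-bladed propeller, no noise, planted +z axis."""
    spec = SyntheticPropellerSpec(n_blades=8, seed=0)
    domain, truth = generate_propeller(spec)
    return spec, domain, truth


@pytest.fixture(scope="session")
def tblr1_noiseless():
    spec = tblr1_like_spec(noise=0.0, seed=0)
    domain, truth = generate_propeller(spec)
    return spec, domain, truth


@pytest.fixture(scope="session")
def tblr1_noisy():
    spec = tblr1_like_spec(noise=0.05, seed=1)
    domain, truth = generate_propeller(spec)
    return spec, domain, truth


@pytest.fixture(scope="session")
def tblr1_analysis(tblr1_noisy):
    """Segmentation, motif alignment, hydrogen bonds, tetrads, frame and
    projection for the TBLR1-like stand-in (computed once per session)."""
    spec, domain, truth = tblr1_noisy
    seg = segment_blades(domain)
    sup = superpose_blades(domain, seg)
    motif = assign_motif_positions(seg, sup, domain)
    hbonds = detect_hbonds(domain)
    tetrads = identify_tetrads(motif, domain, hbonds)
    asps = {t.members["D"] for t in tetrads if t.members["D"] is not None}
    frame = compute_axis(domain, anchor_residues=asps)
    projection = interpolate_missing(project_residues(domain, frame, "C"), domain)
    return dict(spec=spec, domain=domain, truth=truth, segmentation=seg,
                superposition=sup, motif=motif, hbonds=hbonds, tetrads=tetrads,
                frame=frame, projection=projection)
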