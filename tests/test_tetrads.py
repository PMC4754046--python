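"""Hydrogen-bond detection and DHSW tetrad identification."""

import numpy as np
import pytest

from propellervar import detect_hbonds, identify_tetrads, generate_propeller
from propellervar.structure import AtomRecord, DomainStructure, ResidueRecord
from propellervar.synth import SyntheticPropellerSpec
from propellervar.tetrads import MAINCHAIN_ATOMS, _polar_atoms, _antecedent_pos


def _pair_domain(distance):
    """Ser OG donor and Asp OD1 acceptor at the given separation, with valid
    donor geometry (CB behind the OG)."""
    ser = ResidueRecord(1, "SER", (
        AtomRecord("CA", "C", np.array([0.0, 0.0, 0.0])),
        AtomRecord("CB", "C", np.array([-1.0, 0.0, 0.0])),
        AtomRecord("OG", "O", np.array([0.5, 0.0, 0.0])),
    ))
    asp = ResidueRecord(3, "ASP", (
        AtomRecord("CA", "C", np.array([0.5 + distance + 2.0, 0.0, 0.0])),
        AtomRecord("CG", "C", np.array([0.5 + distance + 1.0, 0.0, 0.0])),
        AtomRecord("OD1", "O", np.array([0.5 + distance, 0.0, 0.0])),
    ))
    return DomainStructure("pair", "A", (ser, asp), (1, 3), (2,))


def test_constructed_pair_within_cutoff_is_one_bond():
    bonds = detect_hbonds(_pair_domain(2.9))
    assert len(bonds) == 1
    b = bonds[0]
    assert b.donor == (1, "OG") and b.acceptor == (3, "OD1")
    assert b.distance == pytest.approx(2.9)
    assert b.bond_class == "sidechain-sidechain"


def test_pair_beyond_cutoff_is_no_bond():
    assert detect_hbonds(_pair_domain(3.6), cutoff=3.5) == []


def test_angle_criterion_rejects_acceptor_behind_donor():
    dom = _pair_domain(2.9)
    # move the Ser CB to the acceptor side: antecedent-donor-acceptor < 90 deg
    ser = dom.residues[0]
    atoms = tuple(AtomRecord("CB", "C", np.array([1.5, 0.0, 0.0]))
                  if a.atom_name == "CB" else a for a in ser.atoms)
    dom2 = DomainStructure("pair", "A",
                           (ResidueRecord(1, "SER", atoms), dom.residues[1]),
                           (1, 3), (2,))
    assert detect_hbonds(dom2) == []


def _brute_force_hbonds(domain, cutoff=3.5):
    """Independent exhaustive scan under the same published criteria."""
    out = set()
    residues = list(domain.residues)
    for rd in residues:
        for ad, roles_d in _polar_atoms(rd):
            if "donor" not in roles_d:
                continue
            ante = _antecedent_pos(rd, ad.atom_name)
            for ra in residues:
                for aa, roles_a in _polar_atoms(ra):
                    if "acceptor" not in roles_a:
                        continue
                    if rd.author_number == ra.author_number:
                        continue
                    same_main = (ad.atom_name in MAINCHAIN_ATOMS
                                 and aa.atom_name in MAINCHAIN_ATOMS)
                    if same_main and abs(rd.author_number - ra.author_number) < 2:
                        continue
                    d = float(np.linalg.norm(ad.position - aa.position))
                    if d > cutoff:
                        continue
                    if ante is not None:
                        v1 = ante - ad.position
                        v2 = aa.position - ad.position
                        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                        if denom > 0 and float(v1 @ v2) / denom > 0:
                            continue
                    out.add(((rd.author_number, ad.atom_name),
                             (ra.author_number, aa.atom_name)))
    return out


def test_detector_equals_exhaustive_all_pairs_oracle(tblr1_noisy):
    _, dom, _ = tblr1_noisy
    detected = {(b.donor, b.acceptor) for b in detect_hbonds(dom)}
    assert detected == _brute_force_hbonds(dom)


def test_planted_tetrad_bonds_all_detected(tblr1_noisy):
    _, dom, truth = tblr1_noisy
    detected = {(b.donor, b.acceptor) for b in detect_hbonds(dom)}
    for bond in truth.planted_hbonds:
        assert bond in detected


def test_planted_sidechain_network_and_no_others(tblr1_noiseless):
    """Undirected sidechain-sidechain bonds among tetrad members equal the
    planted network exactly."""
    _, dom, truth = tblr1_noiseless
    members = set()
    for d in truth.tetrad_members.values():
        members |= {v for v in d.values() if v is not None}
    det = set()
    for b in detect_hbonds(dom):
        if b.bond_class == "sidechain-sidechain" and \
                b.donor[0] in members and b.acceptor[0] in members:
            det.add(frozenset((b.donor, b.acceptor)))
    planted = {frozenset(p) for p in truth.planted_hbonds
               if p[0][1] not in MAINCHAIN_ATOMS and p[1][1] not in MAINCHAIN_ATOMS}
    assert det == planted


def test_tetrad_completeness_and_counts(tblr1_analysis):
    tets = tblr1_analysis["tetrads"]
    seg = tblr1_analysis["segmentation"]
    assert len(tets) <= seg.n_blades
    assert sum(t.complete for t in tets) == 6
    missing_w = [t for t in tets if not t.complete and t.missing_only_trp]
    assert len(missing_w) == 1
    # the conserved aspartate is present in all eight blades
    assert sum(t.members["D"] is not None for t in tets) == 8


def test_blade5_tetrad_members_and_asp_backbone_bonds(tblr1_analysis):
    t5 = [t for t in tblr1_analysis["tetrads"] if t.members["D"] == 370][0]
    assert t5.members == {"D": 370, "H": 348, "S_T": 366, "W": 376}
    assert t5.complete
    donors = sorted(b.donor[0] for b in t5.asp_backbone_bonds)
    assert donors == [349, 372]
    assert all(b.acceptor[1] in ("OD1", "OD2") for b in t5.asp_backbone_bonds)
    assert len(t5.hbonds) >= 3  # His-Asp, Ser-His, Trp-Asp at least


def test_complete_tetrads_occupy_canonical_positions(tblr1_analysis):
    motif = tblr1_analysis["motif"]
    for t in tblr1_analysis["tetrads"]:
        if t.complete:
            positions = sorted(motif.position_of(v) for v in t.members.values())
            assert positions == [4, 22, 26, 32]


def test_mutated_trp_blade_is_incomplete_others_complete():
    spec = SyntheticPropellerSpec(
        n_blades=8, seed=2,
        tetrad_placements=("complete",) * 3 + ("missing_W",) + ("complete",) * 4)
    dom, truth = generate_propeller(spec)
    from propellervar import segment_blades, superpose_blades, assign_motif_positions
    seg = segment_blades(dom)
    motif = assign_motif_positions(seg, superpose_blades(dom, seg), dom)
    tets = identify_tetrads(motif, dom, detect_hbonds(dom))
    status = {t.blade_index: t.complete for t in tets}
    assert status[4] is False and sum(status.values()) == 7


def test_poly_alanine_blade_has_no_members():
    spec = SyntheticPropellerSpec(
        n_blades=8, seed=2,
        tetrad_placements=("complete",) * 7 + ("none",))
    dom, truth = generate_propeller(spec)
    from propellervar import segment_blades, superpose_blades, assign_motif_positions
    seg = segment_blades(dom)
    motif = assign_motif_positions(seg, superpose_blades(dom, seg), dom)
    tets = identify_tetrads(motif, dom, detect_hbonds(dom))
    assert all(t.blade_index != 8 for t in tets)  # record absent for that blade
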