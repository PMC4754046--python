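"""Variant parsing, domain filtering, burial, conservation and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from propellervar import (parse_hgvs_p, parse_variant_table, filter_domain_variants,
                          unique_positions, compute_rsasa, shrake_rupley_sasa,
                          conservation_scores, annotate)
from propellervar.structure import AA1_TO_AA3, AtomRecord, DomainStructure, ResidueRecord
from propellervar.variants import VariantParseError, VariantRecord


# --- HGVS p. parsing ---------------------------------------------------------

@pytest.mark.parametrize("text,expect", [
    ("p.(His441Arg)", ("HIS", 441, "ARG")),
    ("His441Arg", ("HIS", 441, "ARG")),
    ("p.Gly70Asp", ("GLY", 70, "ASP")),
    ("ENSP00000405574.1:p.(Asp370Tyr)", ("ASP", 370, "TYR")),
])
def test_hgvs_parse_accepted_forms(text, expect):
    assert parse_hgvs_p(text) == expect


@pytest.mark.parametrize("text", ["p.441His>Arg", "H441R", "p.(Xyz441Arg)", ""])
def test_hgvs_parse_rejects_malformed(text):
    with pytest.raises(VariantParseError):
        parse_hgvs_p(text)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(ref=st.sampled_from(sorted(AA1_TO_AA3.values())),
       alt=st.sampled_from(sorted(AA1_TO_AA3.values())),
       num=st.integers(min_value=1, max_value=99999))
def test_hgvs_round_trip(ref, alt, num):
    label = f"p.({ref.capitalize()}{num}{alt.capitalize()})"
    assert parse_hgvs_p(label) == (ref, num, alt)


# --- the packaged tables -----------------------------------------------------

def test_table2_counts_and_duplicates(table2_path):
    recs = parse_variant_table(table2_path)
    assert len(recs) == 39
    dom = filter_domain_variants(recs, (153, 514))
    pop = [v for v in dom if v.source_category == "population"]
    diag = [v for v in dom if v.source_category == "diagnostic"]
    assert (len(pop), len(diag)) == (33, 6)
    positions, mult = unique_positions(pop)
    assert len(positions) == 29
    assert sorted(n for n, m in mult.items() if m > 1) == [320, 360, 407, 431]


def test_table2_source_and_allele_count_extraction(table2_path):
    recs = parse_variant_table(table2_path)
    ala475 = [v for v in recs if v.label == "ALA475VAL"][0]
    assert ala475.source_label == "ExAC" and ala475.allele_count == 27
    his441 = [v for v in recs if v.label == "HIS441ARG"][0]
    assert his441.source_category == "diagnostic" and his441.allele_count is None
    assert his441.genomic[0] == "chr3" and his441.genomic[1] == 176750853


def test_table1_domain_filter_excludes_gly70(table1_path):
    recs = parse_variant_table(table1_path)
    assert len(recs) == 7
    dom = filter_domain_variants(recs, (153, 514))
    assert len(dom) == 6
    assert {v.label for v in recs} - {v.label for v in dom} == {"GLY70ASP"}


def test_filter_partition_reconstructs_input(table2_path):
    recs = parse_variant_table(table2_path)
    inside = filter_domain_variants(recs, (300, 400))
    outside = [v for v in recs if not 300 <= v.residue_number <= 400]
    assert sorted(v.label for v in inside + outside) == sorted(v.label for v in recs)
    assert filter_domain_variants([], (1, 10)) == []


def test_unique_positions_multiplicity():
    mk = lambda n, alt: VariantRecord("population", "x", ("ALA", n, alt))
    pos, mult = unique_positions([mk(7, "GLY")])
    assert pos == {7} and mult == {7: 1}
    pos, mult = unique_positions([mk(7, "GLY"), mk(7, "VAL")])
    assert pos == {7} and mult[7] == 2


def test_variant_record_invariants():
    with pytest.raises(ValueError):
        VariantRecord("population", "x", ("ALA", 5, "ALA"))
    with pytest.raises(ValueError):
        VariantRecord("population", "x", ("ALA", 0, "GLY"))


# --- solvent accessibility ---------------------------------------------------

def test_isolated_atom_fully_exposed():
    areas = shrake_rupley_sasa(np.zeros((1, 3)), ["C"], n_points=960)
    r = 1.70 + 1.4
    assert areas[0] == pytest.approx(4 * np.pi * r * r, rel=1e-9)


def test_enclosed_atom_has_zero_exposure():
    # centre atom caged by 26 neighbours on a dense shell
    shell = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    v = np.array([dx, dy, dz], float)
                    shell.append(2.2 * v / np.linalg.norm(v))
    pos = np.vstack([np.zeros(3), shell])
    areas = shrake_rupley_sasa(pos, ["C"] * len(pos), n_points=960)
    assert areas[0] == 0.0


def _extended_gly_peptide():
    pos, el = [], []
    for i in range(5):
        base = np.array([3.9 * i, 0.4 * (-1) ** i, 0.0])
        for name, off in (("N", (-0.9, -0.5, 0.0)), ("CA", (0, 0, 0)),
                          ("C", (0.9, 0.6, 0.2)), ("O", (1.1, 1.8, 0.4))):
            pos.append(base + np.array(off))
            el.append(name[0])
    return np.array(pos), el


def test_sasa_default_density_within_2pct_of_high_density_oracle():
    pos, el = _extended_gly_peptide()
    fast = shrake_rupley_sasa(pos, el, n_points=960)
    oracle = shrake_rupley_sasa(pos, el, n_points=10_000)
    rel = np.abs(fast - oracle) / np.maximum(oracle, 1e-9)
    assert rel.max() <= 0.02


def test_rsasa_monotone_under_added_occluders():
    mk = lambda n, atoms: ResidueRecord(n, "GLY", atoms)
    base = DomainStructure("t", "A", (
        mk(1, (AtomRecord("CA", "C", np.zeros(3)),)),
    ), (1, 1))
    crowded = DomainStructure("t", "A", (
        mk(1, (AtomRecord("CA", "C", np.zeros(3)),)),
        mk(2, (AtomRecord("CA", "C", np.array([3.0, 0.0, 0.0])),)),
        mk(3, (AtomRecord("CA", "C", np.array([0.0, 3.0, 0.0])),)),
    ), (1, 3))
    free = compute_rsasa(base)[1]
    occluded = compute_rsasa(crowded)[1]
    assert occluded < free


def test_rsasa_values_bounded(tblr1_noisy):
    _, dom, _ = tblr1_noisy
    rs = compute_rsasa(dom, n_points=120)
    assert rs and all(0.0 <= v <= 1.0 for v in rs.values())


# --- conservation ------------------------------------------------------------

def _write_msa(tmp_path, rows, name="m.fasta"):
    p = tmp_path / name
    p.write_text("".join(f">s{i}\n{r}\n" for i, r in enumerate(rows)))
    return p


def test_invariant_column_scores_one(tmp_path):
    p = _write_msa(tmp_path, ["AC", "AC", "AC", "AC"])
    prof = conservation_scores(p, "s0", [10, 11])
    assert prof.by_residue[10] == pytest.approx(1.0, abs=0.02)


def test_uniform_column_scores_zero(tmp_path):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = [a + "A" for a in aas] * 25  # 500 rows, first column uniform 20-way
    p = _write_msa(tmp_path, rows)
    prof = conservation_scores(p, "s0", [1, 2])
    assert prof.by_residue[1] == pytest.approx(0.0, abs=0.03)
    assert prof.by_residue[2] == pytest.approx(1.0, abs=0.02)


def test_conservation_permutation_invariant(tmp_path):
    rng = np.random.default_rng(5)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = ["".join(rng.choice(aas, size=8)) for _ in range(40)]
    p1 = _write_msa(tmp_path, rows, "a.fasta")
    order = rng.permutation(len(rows))
    # keep row s0 first so the reference still exists under the same id
    shuffled = [rows[0]] + [rows[i] for i in order if i != 0]
    p2 = _write_msa(tmp_path, shuffled, "b.fasta")
    prof1 = conservation_scores(p1, "s0", list(range(1, 9)))
    prof2 = conservation_scores(p2, "s0", list(range(1, 9)))
    assert np.allclose(prof1.scores, prof2.scores)


def test_conservation_error_paths(tmp_path):
    p = _write_msa(tmp_path, ["ACD", "AC-"])
    with pytest.raises(KeyError):
        conservation_scores(p, "missing", [1, 2, 3])
    with pytest.raises(ValueError, match="residues"):
        conservation_scores(p, "s0", [1, 2])  # length mismatch
    bad = _write_msa(tmp_path, ["ACD", "AC"], "c.fasta")
    with pytest.raises(ValueError, match="unequal"):
        conservation_scores(bad, "s0", [1, 2, 3])


def test_planted_conservation_recovery():
    import tempfile, os
    from propellervar.synth import (tblr1_like_spec, generate_propeller,
                                    planted_conservation_for, generate_msa)
    spec = tblr1_like_spec(noise=0.0, seed=0)
    dom, truth = generate_propeller(spec)
    planted = planted_conservation_for(spec)
    with tempfile.TemporaryDirectory() as td:
        fp = os.path.join(td, "msa.fasta")
        generate_msa(planted, truth.sequence, n_sequences=500, seed=1, path=fp)
        prof = conservation_scores(fp, "reference",
                                   [r.author_number for r in dom.residues])
    assert max(abs(prof.by_residue[n] - planted[n]) for n in planted) <= 0.05


# --- annotation join ---------------------------------------------------------

def test_annotation_join_on_reference_like_domain(tblr1_analysis, table2_path):
    a = tblr1_analysis
    recs = filter_domain_variants(parse_variant_table(table2_path),
                                  a["domain"].domain_range)
    ann = annotate(recs, projection=a["projection"], motif=a["motif"],
                   tetrads=a["tetrads"], domain=a["domain"])
    by_label = {x.variant.label: x for x in ann}
    assert by_label["HIS441ARG"].tetrad_member
    assert by_label["HIS441ARG"].motif_position == 4
    assert by_label["PRO444ARG"].motif_position == 7
    assert not by_label["PRO444ARG"].tetrad_member
    assert by_label["ASN320SER"].multiplicity == 2
    assert all(x.z is not None for x in ann)


def test_variant_at_unresolved_residue_gets_interpolated_z(tblr1_noiseless):
    spec, dom, truth = tblr1_noiseless
    from propellervar import (compute_axis, project_residues, interpolate_missing)
    from propellervar.structure import DomainStructure as DS
    kept = tuple(r for r in dom.residues if r.author_number != 423)
    dom2 = DS(dom.source_id, dom.chain_id, kept, dom.domain_range,
              tuple(sorted(set(dom.missing_numbers) | {423})))
    frame = compute_axis(dom2, anchor_residues={370})
    proj = interpolate_missing(project_residues(dom2, frame, "C"), dom2)
    rec = VariantRecord("population", "ExAC", ("THR", 423, "ALA"))
    ann = annotate([rec], projection=proj, domain=dom2)
    assert ann[0].z_status == "interpolated"


def test_unmapped_variant_warns_but_is_kept(tblr1_analysis):
    rec = VariantRecord("population", "ExAC", ("GLY", 9999, "ASP"))
    with pytest.warns(UserWarning, match="absent"):
        ann = annotate([rec], projection=tblr1_analysis["projection"],
                       domain=tblr1_analysis["domain"])
    assert len(ann) == 1 and ann[0].z is None
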