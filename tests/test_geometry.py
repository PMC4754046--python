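"""Propeller axis, axial projection and interpolation of unresolved residues."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from propellervar import (compute_axis, project_residues, interpolate_missing,
                          generate_propeller)
from propellervar.geometry import AxisMode, DegenerateAxisError, ZEntry, ZProjection
from propellervar.structure import AtomRecord, DomainStructure, ResidueRecord
from propellervar.synth import SyntheticPropellerSpec


def _domain_from_points(points, atom_name="C", extra_ca=True):
    residues = []
    for i, p in enumerate(points, start=1):
        atoms = [AtomRecord(atom_name, atom_name[0], np.asarray(p, float))]
        if extra_ca and atom_name != "CA":
            atoms.append(AtomRecord("CA", "C", np.asarray(p, float)))
        residues.append(ResidueRecord(i, "GLY", tuple(atoms)))
    return DomainStructure("test", "A", tuple(residues), (1, len(points)))


def _rigid_copy(domain, R, t):
    residues = []
    for r in domain.residues:
        atoms = tuple(AtomRecord(a.atom_name, a.element, R @ a.position + t)
                      for a in r.atoms)
        residues.append(ResidueRecord(r.author_number, r.aa3, atoms, r.insertion_code))
    return DomainStructure(domain.source_id, domain.chain_id, tuple(residues),
                           domain.domain_range, domain.missing_numbers)


def test_axis_recovers_planted_direction_exactly(generic_propeller):
    _, dom, truth = generic_propeller
    frame = compute_axis(dom)
    assert abs(frame.axis @ truth.axis) >= 1.0 - 1e-9


@pytest.mark.parametrize("axis", [(1.0, 2.0, 2.0), (0.0, 1.0, 0.0)])
def test_axis_recovers_tilted_planted_direction(axis):
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    spec = SyntheticPropellerSpec(n_blades=8, seed=0, axis_direction=tuple(u))
    dom, truth = generate_propeller(spec)
    frame = compute_axis(dom)
    assert abs(frame.axis @ truth.axis) >= 1.0 - 1e-9


def test_rotation_equivariance_of_axis_and_z(generic_propeller):
    _, dom, _ = generic_propeller
    R = Rotation.from_euler("xyz", [0.4, -1.2, 2.1]).as_matrix()
    rotated = _rigid_copy(dom, R, np.array([3.0, -7.0, 11.0]))
    f0 = compute_axis(dom)
    f1 = compute_axis(rotated)
    assert abs(f1.axis @ (R @ f0.axis)) >= 1.0 - 1e-9
    z0 = project_residues(dom, f0)
    z1 = project_residues(rotated, f1)
    sign = np.sign(f1.axis @ (R @ f0.axis))
    for n in z0.entries:
        assert z1.entries[n].z * sign == pytest.approx(z0.entries[n].z, abs=1e-6)


def test_flat_grid_axis_is_z():
    pts = [(x, y, 0.0) for x in range(5) for y in range(5)]
    dom = _domain_from_points(pts, atom_name="CA", extra_ca=False)
    frame = compute_axis(dom)
    assert abs(frame.axis @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-12)


def test_degenerate_cloud_raises():
    rng = np.random.default_rng(0)
    pts = [(float(x), 2.0 * float(x), 3.0 * float(x)) for x in range(12)]  # collinear
    dom = _domain_from_points(pts, atom_name="CA", extra_ca=False)
    with pytest.raises(DegenerateAxisError):
        compute_axis(dom)


def test_orientation_contract_anchor_mean_above_domain_mean(tblr1_analysis):
    frame, proj = tblr1_analysis["frame"], tblr1_analysis["projection"]
    tets = tblr1_analysis["tetrads"]
    asps = [t.members["D"] for t in tets if t.members["D"] is not None]
    anchor_mean = np.mean([proj.entries[a].z for a in asps])
    assert anchor_mean > np.mean([e.z for e in proj.entries.values()])


def test_projection_trivial_values():
    dom = _domain_from_points([(0, 0, 0), (0, 0, 5), (3, 4, 2)])
    frame_origin = np.zeros(3)
    from propellervar.geometry import PropellerFrame
    frame = PropellerFrame(origin=frame_origin, axis=np.array([0, 0, 1.0]),
                           mode=AxisMode.PRINCIPAL)
    proj = project_residues(dom, frame)
    assert proj.entries[1].z == pytest.approx(0.0)
    assert proj.entries[2].z == pytest.approx(5.0)
    assert all(e.status == "observed" for e in proj.entries.values())


def test_projection_matches_planted_axial_coordinates(tblr1_analysis):
    proj = tblr1_analysis["projection"]
    truth = tblr1_analysis["truth"]
    sigma = tblr1_analysis["spec"].coordinate_noise_sigma
    zs = {n: e.z for n, e in proj.entries.items() if e.status == "observed"}
    planted = truth.planted_z
    shift = np.mean([planted[n] for n in zs]) - np.mean(list(zs.values()))
    # small residual axis tilt from the asymmetric tail contributes ~0.5 A
    tol = max(3 * sigma, 0.1) + 0.5
    for n, z in zs.items():
        assert abs(z - (planted[n] - shift)) < tol


def test_interpolation_linear_and_monotone():
    entries = {10: ZEntry(0.0, "observed"), 12: ZEntry(2.0, "observed"),
               20: ZEntry(0.0, "observed"), 24: ZEntry(4.0, "observed")}
    dom = DomainStructure(
        "t", "A",
        tuple(ResidueRecord(n, "GLY",
                            (AtomRecord("C", "C", np.array([0.0, 0.0, 0.0])),))
              for n in (10, 12, 20, 24)),
        (10, 24), missing_numbers=(11, 13, 14, 15, 16, 17, 18, 19, 21, 22, 23))
    proj = interpolate_missing(ZProjection(entries), dom)
    assert proj.entries[11].z == pytest.approx(1.0)   # midpoint of a 1-gap
    for m, want in [(21, 1.0), (22, 2.0), (23, 3.0)]:  # 3-gap between 0 and 4
        assert proj.entries[m].z == pytest.approx(want)
        assert proj.entries[m].status == "interpolated"
    # endpoints unchanged
    assert proj.entries[20].z == 0.0 and proj.entries[24].z == 4.0


def test_boundary_gaps_left_absent_with_warning():
    entries = {5: ZEntry(1.0, "observed"), 6: ZEntry(2.0, "observed")}
    dom = DomainStructure(
        "t", "A",
        tuple(ResidueRecord(n, "GLY",
                            (AtomRecord("C", "C", np.array([0.0, 0.0, 0.0])),))
              for n in (5, 6)),
        (3, 6), missing_numbers=(3, 4))
    with pytest.warns(UserWarning, match="boundary"):
        proj = interpolate_missing(ZProjection(entries), dom)
    assert 3 not in proj.entries and 4 not in proj.entries


def test_interpolation_recovers_planted_z_for_deleted_residues(tblr1_noiseless):
    spec, dom, truth = tblr1_noiseless
    from propellervar import extract_domain
    from propellervar.structure import DomainStructure as DS
    deleted = [230, 231, 300, 415, 500]
    kept = tuple(r for r in dom.residues if r.author_number not in deleted)
    nums = [r.author_number for r in kept]
    dom2 = DS(dom.source_id, dom.chain_id, kept, dom.domain_range,
              tuple(sorted(set(dom.missing_numbers) | set(deleted))))
    frame = compute_axis(dom2, anchor_residues={370, 328})
    proj = interpolate_missing(project_residues(dom2, frame, "C"), dom2)
    sign = np.sign(frame.axis @ truth.axis)
    zs = {n: e.z for n, e in proj.entries.items()}
    shift = np.mean([truth.planted_z[n] for n in zs]) - sign * np.mean(list(zs.values()))
    for m in deleted:
        assert proj.entries[m].status == "interpolated"
        lo = max(n for n in zs if n < m and proj.entries[n].status == "observed")
        hi = min(n for n in zs if n > m and proj.entries[n].status == "observed")
        bound = max(abs(truth.planted_z[lo] - truth.planted_z[hi]), 1.0) + 0.6
        assert abs(sign * zs[m] + shift - truth.planted_z[m]) <= bound
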