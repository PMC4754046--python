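"""Synthetic propeller, variant-set and alignment generators with ground truth.

Every analysis stage of the package can be exercised without downloads: the
generator emits an idealized N-bladed propeller (PDB-writable), a variant TSV
in the collated-table dialect, and a FASTA alignment, together with the
planted ground truth (axis, blade ranges, motif positions, tetrad statuses,
per-residue axial coordinates, variant labels).

Blade geometry
--------------
Each blade is a four-strand hydrogen-bond ladder in a local slab frame
(x = tangential strand spacing 4.8 A, y = radial, z = axial), with the
strands tilted so the per-residue axial rise is 2 A (real propeller strands
are inclined to the axis, so their axial rise is well below the 3.3 A
backbone rise).  The tetrad positions 4/22/26/32 sit at the top of the
blade: the His in the loop shoulder above the sheet, Ser/Thr and Asp at the
tops of adjacent strands, Trp across the top hairpin.  Pseudo sidechain
atoms for tetrad members are placed algorithmically to satisfy the
geometric hydrogen-bond criterion (distance ~2.85 A, donor angle valid),
including the Asp carboxylate bonds to the main-chain N of the residue
after the His (motif 5) and of the residue two below the Asp (motif 28).
Blades are arranged with n-fold rotational symmetry about the planted axis.

Idealizations: no velcro closure (each blade is a self-contained ladder),
loops may contain non-physical CA-CA gaps, and only tetrad members carry
sidechain atoms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import AtomRecord, DomainStructure, ResidueRecord, AA1_TO_AA3

__all__ = [
    "SyntheticPropellerSpec",
    "SyntheticVariantSpec",
    "GroundTruth",
    "generate_propeller",
    "generate_variants",
    "generate_msa",
    "tblr1_like_spec",
    "TBLR1_DOMAIN_RANGE",
    "TBLR1_BLADE_STARTS",
    "TBLR1_HOTSPOT_POSITIONS",
    "hotspot_residues_for",
    "planted_conservation_for",
    "generate_external_scores",
]

MOTIF_CORE = 32          # template positions 1..32 are the motif
TEMPLATE_LEN = 42        # default repeat length (core + inter-blade loop)
HBOND_LEN = 2.85         # planted donor-acceptor distance, Angstrom

# template CA coordinates per motif position (x tangential, y radial, z axial)
_TEMPLATE_XY: dict[int, tuple[float, float]] = {
    1: (1.0, -3.0), 2: (2.2, -2.8), 3: (3.2, -2.5),
    4: (5.0, 3.4), 5: (4.2, 3.0), 6: (3.8, 1.6),
    7: (4.8, 0.0), 8: (4.8, 0.0), 9: (4.8, 0.0), 10: (4.8, 0.0),
    11: (4.8, 0.0), 12: (4.8, 0.0), 13: (4.8, 0.0),
    14: (3.6, -0.9), 15: (1.2, -0.9),
    16: (0.0, 0.0), 17: (0.0, 0.0), 18: (0.0, 0.0), 19: (0.0, 0.0),
    20: (0.0, 0.0), 21: (0.0, 0.0), 22: (0.0, 0.0),
    23: (1.5, -1.2), 24: (4.8, -1.5), 25: (8.1, -1.2),
    26: (9.6, 0.0), 27: (9.6, 0.0), 28: (9.6, 0.0),
    29: (11.8, 0.4),
    30: (14.4, 0.0), 31: (14.4, 0.0), 32: (14.4, 0.0),
    33: (15.8, 0.6), 34: (16.6, 0.9), 35: (17.0, 1.0), 36: (17.0, 0.9),
    37: (16.8, 0.6), 38: (16.4, 0.2), 39: (16.0, -0.4), 40: (15.5, -1.0),
    41: (15.0, -1.6), 42: (14.4, -2.2),
}
_TEMPLATE_Z: dict[int, float] = {
    1: 0.5, 2: 2.5, 3: 5.0,
    4: 7.2, 5: 6.5, 6: 6.7,
    7: 7.0, 8: 5.0, 9: 3.0, 10: 1.0, 11: -1.0, 12: -3.0, 13: -5.0,
    14: -6.5, 15: -6.8,
    16: -5.0, 17: -3.0, 18: -1.0, 19: 1.0, 20: 3.0, 21: 5.0, 22: 7.0,
    23: 8.7, 24: 9.5, 25: 8.7,
    26: 7.0, 27: 5.0, 28: 3.0, 29: 2.0, 30: 3.0, 31: 5.0, 32: 7.0,
    33: 6.0, 34: 4.5, 35: 3.0, 36: 1.5, 37: 0.0, 38: -1.5, 39: -3.0,
    40: -4.2, 41: -5.0, 42: -4.5,
}
_Z_SPAN = 16.3  # native axial extent of the template, for thickness scaling

# strand definitions: (positions, rung partner side for the carbonyl O)
# O points +x toward the next strand slot; N points -x.  The outer hairpin
# strand C2 has no +x neighbour inside the blade, so its O points radially.
_STRAND_POSITIONS = {
    "D": list(range(7, 14)),
    "B": list(range(16, 23)),
    "C1": [26, 27, 28],
    "C2": [30, 31, 32],
}
_STRAND_OF_POS = {p: s for s, ps in _STRAND_POSITIONS.items() for p in ps}

# default residue identity per motif position (WD40-flavoured filler)
_DEFAULT_AA = {
    1: "GLY", 2: "SER", 3: "ASN", 4: "HIS", 5: "THR", 6: "GLY", 7: "PRO",
    8: "VAL", 9: "LEU", 10: "SER", 11: "VAL", 12: "ALA", 13: "PHE",
    14: "GLY", 15: "GLU", 16: "GLY", 17: "LYS", 18: "ASN", 19: "ILE",
    20: "VAL", 21: "LEU", 22: "SER", 23: "GLY", 24: "SER", 25: "ASN",
    26: "ASP", 27: "LYS", 28: "THR", 29: "GLY", 30: "ALA", 31: "VAL",
    32: "TRP", 33: "ASN", 34: "LEU", 35: "GLU", 36: "THR", 37: "GLY",
    38: "GLN", 39: "GLU", 40: "SER", 41: "ALA", 42: "GLY",
}
_TETRAD_AA = {4: "HIS", 22: "SER", 26: "ASP", 32: "TRP"}

# TBLR1-like preset: blade starts anchored on the known motif-position
# assignments (His213=4, Leu282=21, Asp328=26, His348=4/Asp370=26/Trp376=32,
# His441=4, Pro444=7); blades 1, 6 and 8 are unanchored and evenly spaced.
TBLR1_DOMAIN_RANGE = (153, 514)
TBLR1_BLADE_STARTS = (162, 210, 262, 303, 345, 390, 438, 480)
# top-face solvent-exposed template positions supplied as the hotspot list
TBLR1_HOTSPOT_POSITIONS = (5, 7, 23, 25)

# residue identities fixed by the real TBL1XR1 sequence at variant and
# tetrad-anchor positions
_TBLR1_SEQUENCE_OVERRIDES = {
    153: "GLY", 163: "VAL", 180: "VAL", 199: "SER", 203: "THR", 213: "HIS",
    260: "SER", 265: "HIS", 282: "LEU", 320: "ASN", 321: "THR", 328: "ASP",
    348: "HIS", 349: "THR", 360: "THR", 362: "ASN", 366: "SER", 370: "ASP",
    372: "THR", 376: "TRP", 391: "ASN", 405: "GLY", 407: "ASN", 408: "ASN",
    420: "PHE", 423: "THR", 424: "VAL", 431: "ARG", 439: "THR", 440: "LYS",
    441: "HIS", 444: "PRO", 453: "ASP", 455: "ARG", 475: "ALA", 478: "HIS",
    497: "LYS", 513: "ARG", 514: "LYS",
}


@dataclass(frozen=True)
class SyntheticPropellerSpec:
    n_blades: int = 8
    residues_per_blade: int = TEMPLATE_LEN
    barrel_radius: float = 26.0
    axial_thickness: float = _Z_SPAN
    coordinate_noise_sigma: float = 0.0
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tetrad_placements: tuple[str, ...] = ()   # per blade: complete|missing_W|d_only|none
    seed: int = 0
    # layout overrides (used by the TBLR1-like preset)
    blade_starts: tuple[int, ...] | None = None
    domain_range: tuple[int, int] | None = None
    sequence_overrides: dict[int, str] = field(default_factory=dict)
    source_id: str = "synthetic-propeller"

    def __post_init__(self):
        if self.n_blades < 4:
            raise ValueError("a propeller needs >= 4 blades")
        if self.residues_per_blade < MOTIF_CORE:
            raise ValueError(f"residues_per_blade must be >= {MOTIF_CORE}")
        if self.n_blades * self.residues_per_blade > 10_000:
            raise ValueError("propeller too large (> 10^4 residues)")
        if self.coordinate_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        ax = np.asarray(self.axis_direction, float)
        if not np.isfinite(ax).all() or np.linalg.norm(ax) < 1e-9:
            raise ValueError("axis_direction must be a nonzero finite vector")
        # strand slab must fit inside the ring sector
        sector = 2 * math.pi * self.barrel_radius / self.n_blades
        if sector < 19.0:
            raise ValueError(
                f"barrel_radius {self.barrel_radius} too small for "
                f"{self.n_blades} blades (sector {sector:.1f} < 19 A)"
            )
        if self.tetrad_placements and len(self.tetrad_placements) != self.n_blades:
            raise ValueError("tetrad_placements must have one entry per blade")
        for p in self.tetrad_placements:
            if p not in ("complete", "missing_W", "d_only", "none"):
                raise ValueError(f"unknown tetrad placement {p!r}")

    @property
    def placements(self) -> tuple[str, ...]:
        return self.tetrad_placements or ("complete",) * self.n_blades

    @property
    def starts(self) -> tuple[int, ...]:
        if self.blade_starts is not None:
            return self.blade_starts
        return tuple(1 + k * self.residues_per_blade for k in range(self.n_blades))

    def blade_length(self, k: int) -> int:
        starts = self.starts
        if k + 1 < len(starts):
            return starts[k + 1] - starts[k]
        if self.domain_range is not None:
            return self.domain_range[1] - starts[k] + 1
        return self.residues_per_blade


@dataclass(frozen=True)
class SyntheticVariantSpec:
    n_diagnostic: int = 6
    n_population: int = 29
    z_shift: float = 6.0          # planted mean axial shift of diagnostic residues
    placement: str = "top_face_biased"  # or "uniform"
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_diagnostic < 0 or self.n_population < 0:
            raise ValueError("variant counts must be >= 0")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if self.placement not in ("top_face_biased", "uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class GroundTruth:
    axis: np.ndarray                       # planted unit axis, top face positive
    blade_ranges: list[tuple[int, int]]    # structured core span per blade
    repeat_ranges: list[tuple[int, int]]   # full sequence repeat per blade
    motif_positions: dict[int, int]        # residue -> motif position 1-32 (core only)
    tetrad_members: dict[int, dict[str, int | None]]  # blade (1-based) -> role -> residue
    tetrad_status: dict[int, str]          # blade -> placement string
    planted_hbonds: list[tuple[tuple[int, str], tuple[int, str]]]  # (donor, acceptor)
    planted_z: dict[int, float]            # residue -> axial coord of carbonyl C, pre-noise
    sequence: dict[int, str]               # residue -> aa3
    variant_labels: dict[str, str] = field(default_factory=dict)  # label -> category


# --- geometry helpers -------------------------------------------------------

def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto the given (normalized) axis."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _sphere_dirs(n: int = 362) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _place_bonded(target: np.ndarray, ca: np.ndarray, avoid: np.ndarray,
                  donor_check: tuple[np.ndarray, np.ndarray] | None = None,
                  reach: tuple[float, float] = (1.8, 4.5),
                  clear: float = 3.9) -> np.ndarray:
    """Place a functional atom at HBOND_LEN from *target*, within sidechain
    reach of *ca*, keeping at least *clear* Angstrom from the *avoid* atoms
    (other polar atoms, so no unplanned bond can form even under coordinate
    noise); among valid placements the most isolated one is chosen.

    ``donor_check=(donor_pos, donor_antecedent)``: additionally require the
    intended donor's angle criterion to hold for the placed acceptor.
    """
    cands = target + HBOND_LEN * _sphere_dirs()
    d_ca = np.linalg.norm(cands - ca, axis=1)
    ok = (d_ca >= reach[0]) & (d_ca <= reach[1])
    if donor_check is not None:
        dpos, dante = donor_check
        v1 = dante - dpos
        v2 = cands - dpos
        ok &= (v2 @ v1) <= 0.0  # angle(antecedent-donor-acceptor) >= 90 deg
    if not ok.any():
        raise RuntimeError("tetrad geometry infeasible: no valid placement")
    cands = cands[ok]
    if len(avoid):
        score = np.min(np.linalg.norm(cands[:, None, :] - avoid[None, :, :],
                                      axis=-1), axis=1)
        if (score >= clear).any():
            cands, score = cands[score >= clear], score[score >= clear]
    else:
        score = -np.linalg.norm(cands - ca, axis=1)
    return cands[int(np.argmax(score))]


def _element_of(atom_name: str) -> str:
    return {"N": "N", "O": "O"}.get(atom_name[0], "C")


# --- the propeller builder --------------------------------------------------

def _build_blade_local(length: int, placement: str):
    """Local backbone coordinates per template position for one blade.

    Strand residues carry full N/CA/C/O backbones with rung-forming N/O
    offsets; connector (loop/turn) residues carry a sparse CA + carbonyl-C
    backbone -- only the carbonyl carbon feeds downstream analysis, and a
    physically meandering loop is outside the generator's scope -- except
    motif position 5, whose main-chain N is a planted Asp bond target.
    Returns dict pos -> dict atom_name -> (3,) array.
    """
    cas: dict[int, np.ndarray] = {}
    for pos in range(1, length + 1):
        if pos <= TEMPLATE_LEN:
            x, y = _TEMPLATE_XY[pos]
            z = _TEMPLATE_Z[pos]
        else:  # inter-blade extras: low outer loop climbing back up
            i = pos - TEMPLATE_LEN
            n_extra = length - TEMPLATE_LEN
            x = 14.0 - 0.25 * i
            y = -2.8 - 1.5 * (i % 2)
            z = -4.5 + 4.5 * i / max(n_extra, 1)
        cas[pos] = np.array([x, y, z])

    atoms: dict[int, dict[str, np.ndarray]] = {}
    for pos in range(1, length + 1):
        ca = cas[pos]
        strand = _STRAND_OF_POS.get(pos)
        if strand is not None:
            n = ca + np.array([-0.65, -0.20, 0.0])
            if strand == "C2":
                o = ca + np.array([0.0, 1.23, 0.0])  # radially out: no partner
            else:
                o = ca + np.array([1.23, 0.20, 0.0])  # rung O toward next slot
            c = ca + np.array([0.8, 0.0, -0.7])
            if pos == 28:
                # the Asp's i+2 turn partner: amide N faces back up at the
                # carboxylate (the interaction that maintains the beta turn)
                n = ca + np.array([0.0, 0.45, 0.45])
            atoms[pos] = {"N": n, "CA": ca, "C": c, "O": o}
        else:
            nxt = cas.get(pos + 1)
            if nxt is not None and 1e-6 < np.linalg.norm(nxt - ca) < 6.0:
                c_dir = (nxt - ca) / np.linalg.norm(nxt - ca)
            else:
                c_dir = np.array([0.0, -0.6, 0.8])
            atoms[pos] = {"CA": ca, "C": ca + 0.5 * c_dir}
            if pos == 5:
                prev = cas.get(pos - 1)
                n_dir = ((prev - ca) / np.linalg.norm(prev - ca)
                         if prev is not None else np.array([0.2, 0.8, 0.2]))
                atoms[pos]["N"] = ca + 0.5 * n_dir
    return atoms


def _add_tetrad_sidechains(atoms: dict[int, dict[str, np.ndarray]],
                           placement: str) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """Pseudo sidechains for D/H/S/W members; returns planted (donor, acceptor)
    atom pairs in template-position numbering."""
    if placement in ("none",):
        return []
    placed: list[np.ndarray] = []

    def avoid(owner_pos: int, *exclude: np.ndarray) -> np.ndarray:
        """Polar (N/O) atoms a new functional atom must stay clear of: all
        backbone/sidechain N and O except the owner residue's own atoms (the
        detector ignores same-residue pairs) and the intended bond partner."""
        rows = [p for pos, d in atoms.items() if pos != owner_pos
                for name, p in d.items() if name[0] in "NO"]
        rows += placed
        keep = [r for r in rows
                if not any(np.allclose(r, e) for e in exclude)]
        return np.array(keep)

    bonds: list[tuple[tuple[int, str], tuple[int, str]]] = []
    asp = atoms[26]
    n5, ca5 = atoms[5]["N"], atoms[5]["CA"]
    n28, ca28 = atoms[28]["N"], atoms[28]["CA"]

    # Asp carboxylate: OD1 bonds the main-chain N after the His (motif 5),
    # OD2 the main-chain N two residues below the Asp (motif 28).
    od1 = _place_bonded(n5, asp["CA"], avoid(26, n5), donor_check=(n5, ca5))
    placed.append(od1)
    od2 = _place_bonded(n28, asp["CA"], avoid(26, n28), donor_check=(n28, ca28))
    placed.append(od2)
    mid = 0.5 * (od1 + od2)
    cg = asp["CA"] + 0.6 * (mid - asp["CA"]) / max(np.linalg.norm(mid - asp["CA"]), 1e-6) * 2.0
    cb = asp["CA"] + 0.5 * (cg - asp["CA"])
    asp.update({"CB": cb, "CG": cg, "OD1": od1, "OD2": od2})
    bonds += [((5, "N"), (26, "OD1")), ((28, "N"), (26, "OD2"))]

    if placement == "d_only":
        return bonds

    # His: NE2 donates to Asp OD1; ND1 accepts from Ser OG.
    his = atoms[4]
    ne2 = _place_bonded(od1, his["CA"], avoid(4, od1), reach=(1.2, 4.6))
    placed.append(ne2)
    cd2 = ne2 + 1.3 * (ne2 - od1) / np.linalg.norm(ne2 - od1)  # donor angle = 180
    ser = atoms[22]
    toward_ser = ser["CA"] - his["CA"]
    nd1 = his["CA"] + 2.2 * toward_ser / np.linalg.norm(toward_ser) + np.array([0.0, 0.6, 1.0])
    og = _place_bonded(nd1, ser["CA"], avoid(22, nd1), reach=(1.2, 3.0))
    placed += [nd1, og]
    cb_s = og + 1.3 * (og - nd1) / np.linalg.norm(og - nd1)
    cg_h = his["CA"] + 0.5 * (nd1 - his["CA"])
    cb_h = his["CA"] + 0.3 * (nd1 - his["CA"])
    his.update({"CB": cb_h, "CG": cg_h, "ND1": nd1, "NE2": ne2, "CD2": cd2})
    ser.update({"CB": cb_s, "OG": og})
    bonds += [((4, "NE2"), (26, "OD1")), ((22, "OG"), (4, "ND1"))]

    if placement == "missing_W":
        return bonds

    # Trp: NE1 donates to Asp OD2.
    trp = atoms[32]
    ne1 = _place_bonded(od2, trp["CA"], avoid(32, od2), reach=(1.8, 4.7))
    placed.append(ne1)
    cd1 = ne1 + 1.3 * (ne1 - od2) / np.linalg.norm(ne1 - od2)
    cb_w = trp["CA"] + 0.45 * (ne1 - trp["CA"])
    cg_w = trp["CA"] + 0.7 * (ne1 - trp["CA"])
    trp.update({"CB": cb_w, "CG": cg_w, "CD1": cd1, "NE1": ne1})
    bonds.append(((32, "NE1"), (26, "OD2")))
    return bonds


def _blade_sequence(length: int, placement: str) -> dict[int, str]:
    seq = {}
    for pos in range(1, length + 1):
        aa = _DEFAULT_AA.get(pos, "GLY")
        if pos in _TETRAD_AA:
            if placement == "none":
                aa = "ALA"
            elif placement == "d_only" and pos != 26:
                aa = "ALA"
            elif placement == "missing_W" and pos == 32:
                aa = "LEU"
        seq[pos] = aa
    return seq


def generate_propeller(spec: SyntheticPropellerSpec) -> tuple[DomainStructure, GroundTruth]:
    """Build the propeller and its ground truth.  Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    z_scale = spec.axial_thickness / _Z_SPAN
    R = spec.barrel_radius
    rot_axis = _rotation_to(np.asarray(spec.axis_direction, float))

    starts = spec.starts
    placements = spec.placements
    residues: list[ResidueRecord] = []
    truth = GroundTruth(
        axis=rot_axis @ np.array([0.0, 0.0, 1.0]),
        blade_ranges=[], repeat_ranges=[], motif_positions={},
        tetrad_members={}, tetrad_status={}, planted_hbonds=[],
        planted_z={}, sequence={},
    )

    def to_global(local: np.ndarray, phi: float) -> np.ndarray:
        x, y, z = local
        r_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
        t_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])
        g = (R + y) * r_hat + (x - 7.2) * t_hat + np.array([0.0, 0.0, z])
        return rot_axis @ g

    role_pos = {"D": 26, "H": 4, "S_T": 22, "W": 32}

    for k in range(spec.n_blades):
        start = starts[k]
        length = spec.blade_length(k)
        placement = placements[k]
        phi = -2.0 * math.pi * k / spec.n_blades
        atoms = _build_blade_local(length, placement)
        for pos in atoms:
            for name in atoms[pos]:
                atoms[pos][name] = atoms[pos][name] * np.array([1.0, 1.0, z_scale])
        planted = _add_tetrad_sidechains(atoms, placement)
        seq = _blade_sequence(length, placement)

        truth.repeat_ranges.append((start, start + length - 1))
        truth.blade_ranges.append((start + 6, start + 31))  # strand core 7..32
        truth.tetrad_status[k + 1] = placement
        members: dict[str, int | None] = {}
        for role, pos in role_pos.items():
            aa = seq[pos]
            expect = {"D": {"ASP"}, "H": {"HIS"}, "S_T": {"SER", "THR"}, "W": {"TRP"}}[role]
            members[role] = start + pos - 1 if aa in expect else None
        truth.tetrad_members[k + 1] = members
        for (dpos, dname), (apos, aname) in planted:
            truth.planted_hbonds.append(
                ((start + dpos - 1, dname), (start + apos - 1, aname)))

        for pos in range(1, length + 1):
            num = start + pos - 1
            if pos <= MOTIF_CORE:
                truth.motif_positions[num] = pos
            aa = seq[pos]
            truth.sequence[num] = aa
            rec_atoms = []
            for name, local in atoms[pos].items():
                g = to_global(local, phi)
                if name == "C":
                    truth.planted_z[num] = float((rot_axis.T @ g)[2])
                if spec.coordinate_noise_sigma > 0:
                    g = g + rng.normal(0.0, spec.coordinate_noise_sigma, 3)
                rec_atoms.append(AtomRecord(atom_name=name, element=_element_of(name),
                                            position=g))
            residues.append(ResidueRecord(author_number=num, aa3=aa,
                                          atoms=tuple(rec_atoms)))

    # optional N-terminal tail before the first blade (outer bottom loop)
    if spec.domain_range is not None and spec.domain_range[0] < starts[0]:
        tail = list(range(spec.domain_range[0], starts[0]))
        for i, num in enumerate(tail):
            local = np.array([-6.0 + 0.55 * i, -3.5, (-4.5 + 0.4 * i) * z_scale])
            ca = to_global(local, 0.0)
            c = ca + np.array([0.0, -0.3, 1.2])
            truth.planted_z[num] = float((rot_axis.T @ c)[2])
            truth.sequence[num] = "GLY"
            rec_atoms = []
            for name, g in (("CA", ca), ("C", c)):
                if spec.coordinate_noise_sigma > 0:
                    g = g + rng.normal(0.0, spec.coordinate_noise_sigma, 3)
                rec_atoms.append(AtomRecord(atom_name=name, element=_element_of(name),
                                            position=g))
            residues.append(ResidueRecord(author_number=num, aa3="GLY",
                                          atoms=tuple(rec_atoms)))

    # apply sequence overrides (e.g. the real TBL1XR1 identities)
    overrides = dict(spec.sequence_overrides)
    if overrides:
        fixed = []
        for r in residues:
            aa = overrides.get(r.author_number)
            if aa is not None and aa != r.aa3:
                truth.sequence[r.author_number] = aa
                r = ResidueRecord(author_number=r.author_number, aa3=aa,
                                  atoms=r.atoms, insertion_code=r.insertion_code)
            fixed.append(r)
        residues = fixed

    residues.sort(key=lambda r: (r.author_number, r.insertion_code))
    nums = [r.author_number for r in residues]
    lo, hi = min(nums), max(nums)
    present = set(nums)
    domain = DomainStructure(
        source_id=spec.source_id, chain_id="A", residues=tuple(residues),
        domain_range=(lo, hi),
        missing_numbers=tuple(n for n in range(lo, hi + 1) if n not in present),
    )
    return domain, truth


# --- the TBLR1-like preset --------------------------------------------------

def tblr1_like_spec(noise: float = 0.05, seed: int = 0) -> SyntheticPropellerSpec:
    """Synthetic stand-in emulating the TBLR1 WD40 domain.

    Eight blades on the real TBL1XR1 residue numbering (domain 153-514) with
    the published motif anchors planted, six complete tetrads, one tetrad
    missing only the tryptophan (blade 6) and one blade carrying only the
    conserved aspartate (blade 8), so that the aspartate at motif position 26
    is present in all eight blades.
    """
    return SyntheticPropellerSpec(
        n_blades=8,
        residues_per_blade=TEMPLATE_LEN,
        coordinate_noise_sigma=noise,
        tetrad_placements=("complete", "complete", "complete", "complete",
                           "complete", "missing_W", "complete", "d_only"),
        seed=seed,
        blade_starts=TBLR1_BLADE_STARTS,
        domain_range=TBLR1_DOMAIN_RANGE,
        sequence_overrides=dict(_TBLR1_SEQUENCE_OVERRIDES),
        source_id="synthetic-tblr1-like",
    )


def hotspot_residues_for(spec: SyntheticPropellerSpec,
                         positions: tuple[int, ...] = TBLR1_HOTSPOT_POSITIONS) -> set[int]:
    """Residues at the given top-face template positions across all blades."""
    out = set()
    for k in range(spec.n_blades):
        start = spec.starts[k]
        length = spec.blade_length(k)
        for p in positions:
            if p <= length:
                out.add(start + p - 1)
    return out


def planted_conservation_for(spec: SyntheticPropellerSpec) -> dict[int, float]:
    """Planted per-residue conservation: tetrad positions highly conserved,
    top-face shoulders moderately, strands weakly, loops barely."""
    out = {}
    if spec.domain_range is not None:
        for num in range(spec.domain_range[0], spec.starts[0]):
            out[num] = 0.2
    for k in range(spec.n_blades):
        start = spec.starts[k]
        length = spec.blade_length(k)
        for pos in range(1, length + 1):
            if pos in (4, 22, 26, 32):
                c = 0.95
            elif pos in (5, 7, 21, 23, 24, 25):
                c = 0.7
            elif _STRAND_OF_POS.get(pos):
                c = 0.5
            else:
                c = 0.25
            out[start + pos - 1] = c
    return out


# --- variant generation -----------------------------------------------------

def _pick_biased(rng: np.random.Generator, nums: np.ndarray, zs: np.ndarray,
                 n: int, z_shift: float) -> np.ndarray:
    """Sample n residues whose mean planted z exceeds the domain mean by
    ~z_shift, via a threshold subset chosen by bisection."""
    mean_all = zs.mean()
    lo, hi = zs.min(), zs.max()
    target = min(mean_all + z_shift, hi - 1e-6)
    thresh = lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        sel = zs >= mid
        if sel.sum() < n:
            hi = mid
            continue
        if zs[sel].mean() < target:
            lo = mid
        else:
            hi = mid
        thresh = mid
    sel = np.where(zs >= thresh)[0]
    if len(sel) < n:
        sel = np.argsort(zs)[-n:]
    return nums[rng.choice(sel, size=n, replace=False)]


def generate_variants(spec: SyntheticVariantSpec, truth: GroundTruth,
                      path: str | Path | None = None) -> str:
    """Variant TSV in the collated-table dialect; labels recorded in *truth*.

    Diagnostic residues are sampled with an axial bias achieving the planted
    mean shift toward the top face; population residues uniformly; a fraction
    of population variants is re-drawn at already-used residues (emulating
    recurrent-position duplicates).
    """
    rng = np.random.default_rng(spec.seed)
    nums = np.array(sorted(truth.planted_z))
    zs = np.array([truth.planted_z[n] for n in nums])
    if spec.n_diagnostic + spec.n_population > len(nums):
        raise ValueError("more variants requested than residues available")

    if spec.placement == "top_face_biased" and spec.n_diagnostic > 0:
        diag = _pick_biased(rng, nums, zs, spec.n_diagnostic, spec.z_shift)
    else:
        diag = rng.choice(nums, size=spec.n_diagnostic, replace=False)
    remaining = np.setdiff1d(nums, diag)
    n_dup = int(round(spec.duplicate_fraction * spec.n_population))
    n_base = spec.n_population - n_dup
    pop = list(rng.choice(remaining, size=n_base, replace=False))
    for _ in range(n_dup):
        pop.append(int(rng.choice(pop if pop else remaining)))

    aa1_pool = sorted(AA1_TO_AA3)

    def alt_for(num: int) -> tuple[str, str]:
        ref = truth.sequence[int(num)]
        choices = [AA1_TO_AA3[a] for a in aa1_pool if AA1_TO_AA3[a] != ref]
        return ref, str(rng.choice(choices))

    lines = ["Variation\tSource (allele count)\tLocation (GRCh37)\tRef/alt\t"
             "Predicted amino acid change"]
    truth.variant_labels = {}
    for num in diag:
        ref, alt = alt_for(num)
        label = f"{ref.capitalize()}{int(num)}{alt.capitalize()}"
        truth.variant_labels[label] = "diagnostic"
        lines.append(f"Diagnostic\tDDD\t\t\tp.({label})")
    for num in pop:
        ref, alt = alt_for(num)
        label = f"{ref.capitalize()}{int(num)}{alt.capitalize()}"
        truth.variant_labels.setdefault(label, "population")
        lines.append(f"Population\tExAC (1)\t\t\t{label}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# --- MSA generation ---------------------------------------------------------

def _p_consensus_for(score: float) -> float:
    """Consensus probability whose (consensus vs uniform-rest) distribution
    has normalized entropy 1 - score; solved by bisection."""
    target_h = (1.0 - score) * math.log(20.0)

    def h(p):
        if p >= 1.0 - 1e-12:
            return 0.0
        q = (1.0 - p) / 19.0
        return -(p * math.log(p) + 19.0 * q * math.log(q))

    lo, hi = 0.05, 1.0 - 1e-9  # h is decreasing on [1/20, 1]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if h(mid) > target_h:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_msa(planted_conservation: dict[int, float], sequence: dict[int, str],
                 n_sequences: int = 500, seed: int = 0,
                 reference_id: str = "reference",
                 path: str | Path | None = None) -> str:
    """FASTA alignment with planted per-column conservation.

    Column order follows sorted residue numbers; the first row is the
    ungapped reference (the true domain sequence).  Each column realizes an
    exact consensus-vs-uniform composition whose normalized entropy matches
    1 - planted score (counts rounded to the sample size, rows shuffled), so
    the planted value is carried by the sample itself rather than only in
    expectation.
    """
    from .structure import AA3_TO_AA1
    rng = np.random.default_rng(seed)
    nums = sorted(planted_conservation)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    ref_row = "".join(AA3_TO_AA1.get(sequence[n], "A") for n in nums)
    rows = [ref_row]
    probs = [_p_consensus_for(planted_conservation[n]) for n in nums]
    others = {a: [b for b in aas if b != a] for a in aas}
    n_rest = n_sequences - 1
    cols = []
    for j, n in enumerate(nums):
        cons = ref_row[j]
        n_cons = int(round(probs[j] * n_rest))
        col = [cons] * n_cons
        pool = others[cons]
        for i in range(n_rest - n_cons):  # spread the remainder evenly
            col.append(pool[i % len(pool)])
        cols.append(rng.permutation(np.array(col)))
    mat = np.array(cols).T  # (n_sequences-1, n_cols)
    for i in range(n_sequences - 1):
        rows.append("".join(mat[i]))
    out = []
    for i, row in enumerate(rows):
        name = reference_id if i == 0 else f"seq{i:04d}"
        out.append(f">{name}\n{row}")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# --- external score emulation -----------------------------------------------

def generate_external_scores(truth: GroundTruth, conservation: dict[int, float],
                             seed: int = 0, path: str | Path | None = None) -> str:
    """Synthetic PolyPhen-like (high = damaging) and SIFT-like (low =
    damaging) scores correlated with axial position and conservation."""
    rng = np.random.default_rng(seed)
    zs = np.array(list(truth.planted_z.values()))
    z_mu, z_sd = zs.mean(), zs.std() or 1.0
    lines = ["Variant\tPolyPhen\tSIFT"]
    for label in truth.variant_labels:
        num = int("".join(ch for ch in label if ch.isdigit()))
        zc = (truth.planted_z.get(num, z_mu) - z_mu) / z_sd
        cons = conservation.get(num, 0.3)
        logit = 1.2 * zc + 3.0 * (cons - 0.5) + rng.normal(0, 0.5)
        pph = 1.0 / (1.0 + math.exp(-logit))
        sift = min(1.0, max(0.0, 1.0 - pph + rng.normal(0, 0.05)))
        lines.append(f"{label}\t{pph:.3f}\t{sift:.3f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
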