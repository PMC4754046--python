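"""Hydrogen-bond detection and DHSW tetrad identification.

Each WD40 blade is thermostabilized by an Asp-His-Ser/Thr-Trp sidechain
hydrogen-bond network at motif positions 26/4/22/32.  Crystal structures at
typical resolution lack hydrogens, so bonds are called on heavy-atom
geometry alone: donor-acceptor distance below a cutoff plus an
antecedent-donor-acceptor angle of at least 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import DomainStructure, ResidueRecord

__all__ = [
    "HydrogenBond",
    "TetradRecord",
    "detect_hbonds",
    "identify_tetrads",
    "DEFAULT_HBOND_CUTOFF",
]

DEFAULT_HBOND_CUTOFF = 3.5  # Angstrom, heavy-atom donor-acceptor distance

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Sidechain N/O atoms able to donate a hydrogen (His N-N roles are accepted
# in either direction: tautomer/protonation is not modelled).
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": set(),
}
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}

# covalent antecedent of each polar atom, for the angle criterion
_ANTECEDENT = {
    "N": "CA", "O": "C", "OXT": "C",
    "OD1": "CG", "OD2": "CG", "ND2": "CG", "OE1": "CD", "OE2": "CD",
    "NE2": "CD2", "ND1": "CG", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "NZ": "CE", "OG": "CB", "OG1": "CB", "NE1": "CD1", "OH": "CZ",
}
# Gln NE2 antecedent differs from His NE2; resolved per residue below.
_ANTECEDENT_BY_RES = {("GLN", "NE2"): "CD", ("HIS", "NE2"): "CD2"}


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[int, str]      # (residue_number, atom_name)
    acceptor: tuple[int, str]
    distance: float             # Angstrom
    bond_class: str             # sidechain-sidechain | sidechain-mainchain | mainchain-mainchain

    def involves(self, residue_number: int) -> bool:
        return residue_number in (self.donor[0], self.acceptor[0])


def _polar_atoms(res: ResidueRecord):
    """Yield (atom, kind) where kind is a set of roles {'donor','acceptor'}."""
    donors = _SIDECHAIN_DONORS.get(res.aa3, set())
    acceptors = _SIDECHAIN_ACCEPTORS.get(res.aa3, set())
    for a in res.atoms:
        roles = set()
        if a.atom_name == "N" and res.aa3 != "PRO":
            roles.add("donor")
        if a.atom_name in ("O", "OXT"):
            roles.add("acceptor")
        if a.atom_name in donors:
            roles.add("donor")
        if a.atom_name in acceptors:
            roles.add("acceptor")
        if roles:
            yield a, roles


def _antecedent_pos(res: ResidueRecord, atom_name: str) -> np.ndarray | None:
    name = _ANTECEDENT_BY_RES.get((res.aa3, atom_name), _ANTECEDENT.get(atom_name))
    if name is None:
        return None
    a = res.atom(name)
    return None if a is None else a.position


def _classify(donor_name: str, acceptor_name: str) -> str:
    d_main = donor_name in MAINCHAIN_ATOMS
    a_main = acceptor_name in MAINCHAIN_ATOMS
    if d_main and a_main:
        return "mainchain-mainchain"
    if d_main or a_main:
        return "sidechain-mainchain"
    return "sidechain-sidechain"


def detect_hbonds(domain: DomainStructure, cutoff: float = DEFAULT_HBOND_CUTOFF,
                  selection: str = "all") -> list[HydrogenBond]:
    """Geometric hydrogen bonds between N/O heavy atoms.

    Criterion: donor-acceptor distance <= cutoff and antecedent-donor-acceptor
    angle >= 90 degrees (the acceptor must sit on the hydrogen side of the
    donor).  Same-residue pairs are excluded, as are mainchain-mainchain
    pairs of sequence-adjacent residues (covalent neighbourhood).  Each
    qualifying (donor atom, acceptor atom) pair is listed once, ordered by
    (donor residue, donor atom, acceptor residue, acceptor atom).

    ``selection``: all | sidechain_only | mainchain_only (filters by class).
    """
    if selection not in ("all", "sidechain_only", "mainchain_only"):
        raise ValueError(f"unknown selection {selection!r}")

    atoms = []  # (res, atom, roles)
    for res in domain.residues:
        for a, roles in _polar_atoms(res):
            atoms.append((res, a, roles))
    if not atoms:
        return []
    pos = np.array([a.position for _, a, _ in atoms])
    # neighbour search on the distance matrix; domains are a few thousand atoms
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    cut2 = cutoff * cutoff

    bonds = []
    n = len(atoms)
    for i in range(n):
        res_d, atom_d, roles_d = atoms[i]
        if "donor" not in roles_d:
            continue
        ante = _antecedent_pos(res_d, atom_d.atom_name)
        for j in range(n):
            if i == j:
                continue
            res_a, atom_a, roles_a = atoms[j]
            if "acceptor" not in roles_a:
                continue
            if res_d.author_number == res_a.author_number and res_d.insertion_code == res_a.insertion_code:
                continue
            if d2[i, j] > cut2:
                continue
            cls = _classify(atom_d.atom_name, atom_a.atom_name)
            if cls == "mainchain-mainchain" and abs(res_d.author_number - res_a.author_number) < 2:
                continue  # peptide-bond geometry, not a hydrogen bond
            if selection == "sidechain_only" and cls == "mainchain-mainchain":
                continue
            if selection == "mainchain_only" and cls != "mainchain-mainchain":
                continue
            if ante is not None:
                v1 = ante - atom_d.position
                v2 = atom_a.position - atom_d.position
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom > 0 and (v1 @ v2) / denom > 0.0:  # angle < 90 deg
                    continue
            bonds.append(HydrogenBond(
                donor=(res_d.author_number, atom_d.atom_name),
                acceptor=(res_a.author_number, atom_a.atom_name),
                distance=float(np.sqrt(d2[i, j])),
                bond_class=cls,
            ))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


# --- DHSW tetrads -----------------------------------------------------------

# expected residue identity at each tetrad motif position
TETRAD_POSITIONS = {26: ("D", {"ASP"}), 4: ("H", {"HIS"}),
                    22: ("S_T", {"SER", "THR"}), 32: ("W", {"TRP"})}


@dataclass(frozen=True)
class TetradRecord:
    """One blade's Asp-His-Ser/Thr-Trp tetrad.

    ``members`` maps role (D/H/S_T/W at motif positions 26/4/22/32) to the
    residue number, or None when the position is absent or holds the wrong
    residue type.  Completeness is a sequence-identity property; the
    hydrogen-bond network is reported alongside, never used to demote it.
    """

    blade_index: int
    members: dict[str, int | None]
    complete: bool
    hbonds: tuple[HydrogenBond, ...] = ()
    asp_backbone_bonds: tuple[HydrogenBond, ...] = ()

    @property
    def missing_roles(self) -> list[str]:
        return [k for k, v in self.members.items() if v is None]

    @property
    def missing_only_trp(self) -> bool:
        return self.missing_roles == ["W"] or set(self.missing_roles) == {"W"}


def identify_tetrads(motif, domain: DomainStructure,
                     hbonds: list[HydrogenBond]) -> list[TetradRecord]:
    """One record per blade possessing at least one tetrad position.

    *motif* is a :class:`~propellervar.blades.MotifAlignment`.  Member
    hydrogen bonds are those among member residues excluding
    mainchain-mainchain pairs; ``asp_backbone_bonds`` are bonds between the
    Asp carboxylate oxygens and any main-chain nitrogen (the interactions
    that pin the hairpin at the top of each blade).
    """
    by_blade: dict[int, dict[str, int | None]] = {}
    for resnum, (blade, pos) in motif.assignments.items():
        if pos in TETRAD_POSITIONS:
            role, allowed = TETRAD_POSITIONS[pos]
            res = domain.residue(resnum)
            d = by_blade.setdefault(blade, {k: None for k, _ in TETRAD_POSITIONS.values()})
            if res is not None and res.aa3 in allowed:
                d[role] = resnum

    records = []
    for blade in sorted(by_blade):
        members = by_blade[blade]
        member_nums = {v for v in members.values() if v is not None}
        if not member_nums:
            continue
        internal = tuple(
            b for b in hbonds
            if b.donor[0] in member_nums and b.acceptor[0] in member_nums
            and b.bond_class != "mainchain-mainchain"
        )
        asp_bonds: tuple[HydrogenBond, ...] = ()
        if members["D"] is not None:
            asp = members["D"]
            asp_bonds = tuple(
                b for b in hbonds
                if b.acceptor[0] == asp and b.acceptor[1] in ("OD1", "OD2")
                and b.donor[1] == "N"
            )
        records.append(TetradRecord(
            blade_index=blade,
            members=members,
            complete=all(v is not None for v in members.values()),
            hbonds=internal,
            asp_backbone_bonds=asp_bonds,
        ))
    return records
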