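"""Atomic structure model for a single WD40 domain chain.

Reads PDB/mmCIF files (via gemmi), selects one chain, resolves alternate
locations, and exposes a uniform residue/atom data model with explicit
bookkeeping of unresolved (missing) residue numbers.  Author numbering is
used throughout; an optional offset reconciles variant numbering with the
structure's numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "DomainStructure",
    "StructureParseError",
    "ChainNotFoundError",
    "EmptyDomainError",
    "read_structure",
    "extract_domain",
    "get_atom",
    "write_pdb",
    "AA3_TO_AA1",
    "AA1_TO_AA3",
]

# 20 standard residues; non-standard parents handled in _normalize_resname.
AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

# modified residue -> parent amino acid
_PARENT_RESIDUE = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "SEP": "SER",
                   "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


class EmptyDomainError(ValueError):
    """Raised when a domain extraction retains zero residues."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom in PDB naming convention (e.g. ``CA``, ``OD1``)."""

    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with author number and resolved atoms."""

    author_number: int
    aa3: str
    atoms: tuple[AtomRecord, ...]
    insertion_code: str = ""

    @property
    def aa1(self) -> str:
        return AA3_TO_AA1.get(self.aa3, "X")

    def atom(self, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a
        return None

    def __post_init__(self):
        names = [a.atom_name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.aa3}{self.author_number}: duplicate atom names after alt-loc resolution"
            )


@dataclass(frozen=True)
class DomainStructure:
    """An ordered chain segment with missing-residue accounting.

    ``missing_numbers`` are author numbers strictly inside ``domain_range``
    for which no atoms are present (numbering gaps).
    """

    source_id: str
    chain_id: str
    residues: tuple[ResidueRecord, ...]
    domain_range: tuple[int, int]
    missing_numbers: tuple[int, ...] = ()

    def __post_init__(self):
        nums = [(r.author_number, r.insertion_code) for r in self.residues]
        if nums != sorted(nums):
            raise ValueError("residues must be sorted by (author_number, insertion_code)")
        lo, hi = self.domain_range
        for r in self.residues:
            if not lo <= r.author_number <= hi:
                raise ValueError(f"residue {r.author_number} outside domain_range {self.domain_range}")
        if set(self.missing_numbers) & {r.author_number for r in self.residues}:
            raise ValueError("missing_numbers overlap resolved residue numbers")

    def residue(self, author_number: int) -> ResidueRecord | None:
        for r in self.residues:
            if r.author_number == author_number:
                return r
        return None

    @property
    def resolved_numbers(self) -> list[int]:
        return [r.author_number for r in self.residues]

    def coords(self, atom_name: str = "CA") -> tuple[list[int], np.ndarray]:
        """Residue numbers and coordinates for residues that have *atom_name*."""
        nums, xyz = [], []
        for r in self.residues:
            a = r.atom(atom_name)
            if a is not None:
                nums.append(r.author_number)
                xyz.append(a.position)
        return nums, (np.array(xyz) if xyz else np.empty((0, 3)))


def _compute_missing(numbers: list[int], lo: int, hi: int) -> tuple[int, ...]:
    present = set(numbers)
    return tuple(n for n in range(lo, hi + 1) if n not in present)


def _normalize_resname(name: str) -> str | None:
    name = name.strip().upper()
    if name in AA3_TO_AA1:
        return name
    if name in _PARENT_RESIDUE:
        parent = _PARENT_RESIDUE[name]
        warnings.warn(f"non-standard residue {name} mapped to parent {parent}")
        return parent
    return None


def _resolve_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; ties keep file order."""
    best: dict[str, gemmi.Atom] = {}
    for a in raw_atoms:
        prev = best.get(a.name)
        if prev is None or a.occ > prev.occ:
            best[a.name] = a
    # preserve original atom order
    seen = set()
    out = []
    for a in raw_atoms:
        if a.name not in seen and best[a.name] is a:
            seen.add(a.name)
            out.append(a)
        elif a.name not in seen and best[a.name] is not a:
            # the best one appears later; emit it at first appearance position
            seen.add(a.name)
            out.append(best[a.name])
    return out


def read_structure(path: str | Path, format: str = "auto",
                   chain_id: str | None = None) -> DomainStructure:
    """Read a PDB or mmCIF file and return one chain as a :class:`DomainStructure`.

    HETATM compounds other than modified amino acids, waters, and models past
    the first are excluded; alternate locations resolve to highest occupancy.
    ``domain_range`` spans the full observed extent of the chain.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (expected pdb/mmcif/auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as e:
        raise StructureParseError(f"cannot parse {path}: {e}") from e
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if not chain_names:
        raise StructureParseError(f"{path}: no chains in first model")
    if chain_id is None:
        chain_id = chain_names[0]
    if chain_id not in chain_names:
        raise ChainNotFoundError(f"chain {chain_id!r} not in {path} (has {chain_names})")
    chain = model[chain_id]

    residues: list[ResidueRecord] = []
    for res in chain:
        if res.is_water():
            continue
        aa3 = _normalize_resname(res.name)
        if aa3 is None:
            if res.het_flag == "H":
                continue  # ligand / ion
            warnings.warn(f"unrecognized residue {res.name} {res.seqid.num} dropped")
            continue
        atoms = []
        for a in _resolve_altlocs(list(res)):
            if a.is_hydrogen():
                continue
            atoms.append(AtomRecord(
                atom_name=a.name,
                element=a.element.name,
                position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                occupancy=min(max(a.occ, 0.0), 1.0),
                alt_loc=a.altloc if a.altloc else "",
            ))
        if atoms:
            residues.append(ResidueRecord(
                author_number=res.seqid.num,
                aa3=aa3,
                atoms=tuple(atoms),
                insertion_code=res.seqid.icode.strip(),
            ))
    if not residues:
        raise StructureParseError(f"{path}: chain {chain_id} has no amino-acid residues")
    residues.sort(key=lambda r: (r.author_number, r.insertion_code))
    nums = [r.author_number for r in residues]
    lo, hi = min(nums), max(nums)
    return DomainStructure(
        source_id=st.name or path.stem,
        chain_id=chain_id,
        residues=tuple(residues),
        domain_range=(lo, hi),
        missing_numbers=_compute_missing(nums, lo, hi),
    )


def extract_domain(structure: DomainStructure, start: int, end: int) -> DomainStructure:
    """Restrict to author numbers in ``[start, end]``; recompute numbering gaps."""
    if start > end:
        raise ValueError(f"invalid range [{start}, {end}]")
    kept = tuple(r for r in structure.residues if start <= r.author_number <= end)
    if not kept:
        raise EmptyDomainError(f"no residues of {structure.source_id} in [{start}, {end}]")
    nums = [r.author_number for r in kept]
    return replace(
        structure,
        residues=kept,
        domain_range=(start, end),
        # gaps strictly inside the retained span
        missing_numbers=_compute_missing(nums, min(nums), max(nums)),
    )


def get_atom(domain: DomainStructure, residue_number: int, atom_name: str) -> AtomRecord | None:
    """The named atom of the numbered residue, or ``None`` (absence is a value)."""
    res = domain.residue(residue_number)
    if res is None:
        return None
    return res.atom(atom_name)


def write_pdb(domain: DomainStructure, path: str | Path) -> None:
    """Write the domain as a single-chain PDB file (used for synthetic fixtures)."""
    st = gemmi.Structure()
    st.name = domain.source_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(domain.chain_id or "A")
    for r in domain.residues:
        res = gemmi.Residue()
        res.name = r.aa3
        res.seqid = gemmi.SeqId(r.author_number, r.insertion_code or " ")
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.position)
            atom.occ = a.occupancy
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
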