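"""Variant tables, burial and conservation annotation.

Parses the TSV dialect of the collated variant tables (diagnostic de novo
mutations vs presumed-benign population variants), filters to the WD40
domain, computes relative solvent accessibility (Shrake-Rupley) and
alignment-column conservation, and joins every variant to its structural
annotations.  External pathogenicity scores (PolyPhen/SIFT) are consumed
from a table, never computed.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .structure import AA1_TO_AA3, AA3_TO_AA1, DomainStructure
from .geometry import ZProjection
from .blades import MotifAlignment
from .tetrads import TetradRecord

__all__ = [
    "VariantRecord",
    "AnnotatedVariant",
    "ConservationProfile",
    "VariantParseError",
    "parse_hgvs_p",
    "parse_variant_table",
    "filter_domain_variants",
    "unique_positions",
    "compute_rsasa",
    "shrake_rupley_sasa",
    "conservation_scores",
    "read_external_scores",
    "annotate",
    "MAX_ASA",
    "VDW_RADII",
]


class VariantParseError(ValueError):
    """A variant table row could not be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    source_category: str               # diagnostic | population
    source_label: str                  # e.g. DDD, ExAC, dbSNP
    protein_change: tuple[str, int, str]  # (ref_aa3, residue_number, alt_aa3)
    allele_count: int | None = None
    genomic: tuple[str, int, str, str] | None = None  # (chrom, pos, ref, alt), opaque

    def __post_init__(self):
        ref, num, alt = self.protein_change
        if ref == alt:
            raise ValueError(f"synonymous change {ref}{num}{alt} is not a missense variant")
        if num < 1:
            raise ValueError(f"residue number {num} must be >= 1")

    @property
    def residue_number(self) -> int:
        return self.protein_change[1]

    @property
    def label(self) -> str:
        ref, num, alt = self.protein_change
        return f"{ref}{num}{alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: VariantRecord
    z: float | None = None
    z_status: str | None = None          # observed | interpolated
    rsasa: float | None = None           # 0-1
    conservation: float | None = None    # 0-1
    motif_position: int | None = None    # 1-32
    blade_index: int | None = None
    tetrad_member: bool = False
    hotspot: bool = False
    external_scores: dict[str, float] = field(default_factory=dict)
    multiplicity: int = 1                # variants at this residue across the table


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation (1 - normalized Shannon entropy) of an MSA."""

    scores: np.ndarray          # per alignment column, 0-1
    gap_fraction: np.ndarray    # per column
    n_sequences: int
    by_residue: dict[int, float]  # mapped onto domain numbering via the reference row

    def __post_init__(self):
        if len(self.scores) != len(self.gap_fraction):
            raise ValueError("scores and gap_fraction must have equal length")


# --- HGVS p. parsing --------------------------------------------------------

_HGVS_P = re.compile(
    r"^(?:[A-Za-z0-9_.]+:)?(?:p\.)?\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$"
)


def parse_hgvs_p(text: str) -> tuple[str, int, str]:
    """Parse three-letter protein HGVS, e.g. ``p.(His441Arg)`` or ``His441Arg``.

    Returns (ref_aa3 upper-case, residue number, alt_aa3 upper-case).
    """
    m = _HGVS_P.match(text.strip())
    if not m:
        raise VariantParseError(f"cannot parse protein change {text!r}")
    ref, num, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for aa in (ref, alt):
        if aa not in AA3_TO_AA1:
            raise VariantParseError(f"unknown amino acid {aa!r} in {text!r}")
    return ref, num, alt


_SOURCE_COUNT = re.compile(r"^(.*?)\s*\((\d+)\)\s*$")
_LOCATION = re.compile(r"^(chr[\w]+):(\d+)$")


def _parse_row(row: pd.Series, line_no: int) -> VariantRecord:
    category = str(row.get("Variation", "")).strip().lower()
    if category not in ("diagnostic", "population"):
        raise VariantParseError(f"line {line_no}: unknown category {row.get('Variation')!r}")
    source = str(row.get("Source (allele count)", row.get("Source", ""))).strip()
    allele = None
    m = _SOURCE_COUNT.match(source)
    if m:
        source, allele = m.group(1).strip(), int(m.group(2))
    genomic = None
    loc = str(row.get("Location (GRCh37)", "")).strip()
    m = _LOCATION.match(loc)
    if m:
        ref_alt = str(row.get("Ref/alt", "")).strip()
        ra = ref_alt.split("/") if "/" in ref_alt else ["", ""]
        genomic = (m.group(1), int(m.group(2)), ra[0], ra[1])
    change_text = str(row.get("Predicted amino acid change",
                              row.get("Protein change", ""))).strip()
    try:
        change = parse_hgvs_p(change_text)
    except VariantParseError as e:
        raise VariantParseError(f"line {line_no}: {e}") from e
    return VariantRecord(source_category=category, source_label=source,
                         protein_change=change, allele_count=allele, genomic=genomic)


def parse_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV (columns: Variation, Source (allele count),
    Location (GRCh37), Ref/alt, Predicted amino acid change)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "Variation" not in df.columns:
        raise VariantParseError(f"{path}: missing 'Variation' header column")
    records = []
    for idx, row in df.iterrows():
        records.append(_parse_row(row, line_no=idx + 2))  # 1-based + header
    return records


def filter_domain_variants(variants: list[VariantRecord],
                           domain_range: tuple[int, int]) -> list[VariantRecord]:
    """Keep variants whose residue number lies inside the domain; order kept."""
    lo, hi = domain_range
    return [v for v in variants if lo <= v.residue_number <= hi]


def unique_positions(variants: list[VariantRecord]) -> tuple[set[int], dict[int, int]]:
    """Distinct residue positions and per-residue multiplicity."""
    mult: dict[int, int] = {}
    for v in variants:
        mult[v.residue_number] = mult.get(v.residue_number, 0) + 1
    return set(mult), mult


# --- solvent accessibility --------------------------------------------------

# heavy-atom van der Waals radii (Angstrom), standard protein set
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}

# Maximum ASA of residue X in an extended Gly-X-Gly tripeptide (theoretical,
# Tien et al. 2013), Angstrom^2; used to normalize absolute SASA to rSASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(positions: np.ndarray, elements: list[str],
                       n_points: int = 960, probe: float = 1.4) -> np.ndarray:
    """Per-atom accessible surface area by sphere sampling.

    Each atom's solvent-expanded sphere (vdW + probe) is sampled with
    *n_points* quasi-uniform points; the exposed fraction (points outside all
    other expanded spheres) times the sphere area is the atom's SASA.
    """
    pos = np.asarray(positions, float)
    radii = np.array([VDW_RADII.get(e.upper(), 1.70) + probe for e in elements])
    n = len(pos)
    unit = _sphere_points(n_points)
    areas = np.zeros(n)
    if n == 0:
        return areas
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        # candidate occluders: spheres that can reach atom i's surface
        reach = (radii[i] + radii) ** 2
        nbr = np.where((d2[i] < reach) & (np.arange(n) != i))[0]
        pts = pos[i] + radii[i] * unit
        if len(nbr):
            dd = np.sum((pts[:, None, :] - pos[nbr][None, :, :]) ** 2, axis=-1)
            exposed = np.all(dd >= (radii[nbr] ** 2)[None, :], axis=1)
        else:
            exposed = np.ones(n_points, bool)
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * exposed.mean()
    return areas


def compute_rsasa(domain: DomainStructure, n_points: int = 960,
                  probe: float = 1.4) -> dict[int, float]:
    """Relative per-residue solvent accessibility, clipped to [0, 1].

    Absolute residue SASA is normalized by the extended Gly-X-Gly reference
    for the residue type; values above 1 are clipped with a warning.
    """
    positions, elements, owner = [], [], []
    for r in domain.residues:
        for a in r.atoms:
            positions.append(a.position)
            elements.append(a.element or a.atom_name[0])
            owner.append(r.author_number)
    if not positions:
        return {}
    atom_sasa = shrake_rupley_sasa(np.array(positions), elements,
                                   n_points=n_points, probe=probe)
    per_res: dict[int, float] = {}
    for area, num in zip(atom_sasa, owner):
        per_res[num] = per_res.get(num, 0.0) + float(area)
    out: dict[int, float] = {}
    for r in domain.residues:
        ref = MAX_ASA.get(r.aa3)
        if ref is None:
            continue
        v = per_res.get(r.author_number, 0.0) / ref
        if v > 1.0:
            warnings.warn(f"residue {r.author_number}: rSASA {v:.2f} > 1 clipped")
            v = 1.0
        out[r.author_number] = v
    return out


# --- conservation -----------------------------------------------------------

_AA20 = set(AA1_TO_AA3)


def conservation_scores(msa_path: str | Path, reference_id: str,
                        domain_numbers: list[int],
                        gap_flag_threshold: float = 0.5) -> ConservationProfile:
    """Column conservation mapped to domain numbering via the reference row.

    Score = 1 - H/log(20) where H is the Shannon entropy of the 20-amino-acid
    distribution in the column (gaps excluded).  The reference row's ungapped
    length must equal the number of domain residues; its k-th ungapped column
    maps to the k-th domain residue number.
    """
    with open(msa_path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{msa_path}: empty alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{msa_path}: rows have unequal lengths {sorted(lengths)}")
    ref_rows = [r for r in records if r.id == reference_id]
    if not ref_rows:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    ref = str(ref_rows[0].seq).upper()
    ncol = len(ref)

    seqs = np.array([list(str(r.seq).upper()) for r in records])
    scores = np.zeros(ncol)
    gapf = np.zeros(ncol)
    log20 = math.log(20.0)
    for c in range(ncol):
        col = seqs[:, c]
        aas = col[np.isin(col, list(_AA20))]
        gapf[c] = 1.0 - len(aas) / len(col)
        if len(aas) == 0:
            scores[c] = 0.0
            continue
        _, counts = np.unique(aas, return_counts=True)
        p = counts / counts.sum()
        # plug-in entropy with Miller-Madow small-sample bias correction
        h = float(-(p * np.log(p)).sum()) + (len(counts) - 1) / (2.0 * counts.sum())
        scores[c] = min(1.0, max(0.0, 1.0 - h / log20))
        if gapf[c] > gap_flag_threshold:
            warnings.warn(f"alignment column {c + 1}: gap fraction {gapf[c]:.2f}")

    ref_cols = [c for c in range(ncol) if ref[c] in _AA20]
    if len(ref_cols) != len(domain_numbers):
        raise ValueError(
            f"reference row has {len(ref_cols)} residues but the domain has "
            f"{len(domain_numbers)}"
        )
    by_residue = {num: float(scores[c]) for num, c in zip(domain_numbers, ref_cols)}
    return ConservationProfile(scores=scores, gap_fraction=gapf,
                               n_sequences=len(records), by_residue=by_residue)


# --- external scores and the annotation join --------------------------------

def read_external_scores(path: str | Path) -> dict[str, dict[str, float]]:
    """External per-variant scores keyed by protein change label (e.g.
    His441Arg), column per score name (e.g. PolyPhen, SIFT)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "Variant" not in df.columns:
        raise ValueError(f"{path}: missing 'Variant' column")
    out: dict[str, dict[str, float]] = {}
    score_cols = [c for c in df.columns if c != "Variant"]
    for _, row in df.iterrows():
        ref, num, alt = parse_hgvs_p(row["Variant"])
        key = f"{ref.capitalize()}{num}{alt.capitalize()}"
        out[key] = {c: float(row[c]) for c in score_cols if row[c] != ""}
    return out


def annotate(variants: list[VariantRecord],
             projection: ZProjection | None = None,
             motif: MotifAlignment | None = None,
             tetrads: list[TetradRecord] | None = None,
             rsasa: dict[int, float] | None = None,
             conservation: ConservationProfile | None = None,
             hotspot_residues: set[int] | None = None,
             external_scores: dict[str, dict[str, float]] | None = None,
             domain: DomainStructure | None = None) -> list[AnnotatedVariant]:
    """Left-join every variant to its structural annotations.

    A variant with no structural residue keeps absent annotations and emits a
    warning; it is never silently dropped.  ``tetrad_member`` is true iff the
    residue is a member of any tetrad record; ``hotspot`` comes from the
    supplied top-face list (annotation disabled when the list is absent).
    """
    tetrad_residues: set[int] = set()
    for t in (tetrads or []):
        tetrad_residues |= {v for v in t.members.values() if v is not None}
    _, mult = unique_positions(variants)

    out = []
    for v in variants:
        num = v.residue_number
        if domain is not None:
            res = domain.residue(num)
            if res is None and num not in (domain.missing_numbers or ()):
                warnings.warn(f"variant {v.label}: residue {num} absent from the structure")
            elif res is not None and res.aa3 != v.protein_change[0]:
                warnings.warn(
                    f"variant {v.label}: structure has {res.aa3} at {num}, "
                    f"expected {v.protein_change[0]}"
                )
        z = z_status = None
        if projection is not None:
            e = projection.entries.get(num)
            if e is not None:
                z, z_status = e.z, e.status
        pos = blade = None
        if motif is not None:
            a = motif.assignments.get(num)
            if a is not None:
                blade, pos = a
        key = f"{v.protein_change[0].capitalize()}{num}{v.protein_change[2].capitalize()}"
        out.append(AnnotatedVariant(
            variant=v,
            z=z, z_status=z_status,
            rsasa=None if rsasa is None else rsasa.get(num),
            conservation=None if conservation is None else conservation.by_residue.get(num),
            motif_position=pos, blade_index=blade,
            tetrad_member=num in tetrad_residues,
            hotspot=(num in hotspot_residues) if hotspot_residues is not None else False,
            external_scores=(external_scores or {}).get(key, {}),
            multiplicity=mult[num],
        ))
    return out


def annotated_to_frame(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    """Flat table, one row per variant with all annotation columns."""
    rows = []
    score_names = sorted({k for a in annotated for k in a.external_scores})
    for a in annotated:
        row = {
            "variant": a.variant.label,
            "category": a.variant.source_category,
            "source": a.variant.source_label,
            "residue": a.variant.residue_number,
            "z": a.z, "z_status": a.z_status,
            "rsasa": a.rsasa, "conservation": a.conservation,
            "motif_position": a.motif_position, "blade": a.blade_index,
            "tetrad_member": a.tetrad_member, "hotspot": a.hotspot,
            "multiplicity": a.multiplicity,
        }
        for s in score_names:
            row[s] = a.external_scores.get(s)
        rows.append(row)
    return pd.DataFrame(rows)
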